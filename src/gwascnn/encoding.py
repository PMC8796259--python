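"""Minor-allele additive encoding of the model input matrix.

Each genotype is coded by its minor-allele count — homozygous minor
(aa) 2, heterozygous (Aa) 1, homozygous major (AA) 0 — and missing
calls by -1, giving entries X_mn in {-1, 0, 1, 2} for sample m and SNP
n, with SNPs in genomic order.  The minor allele is designated from the
pooled (cases + controls) allele frequency of the study cohort itself;
ties at exactly 0.5 are broken lexicographically by allele character.
No imputation is applied: the -1 code is fed to the model as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureSet
from .simulate import Cohort

__all__ = ["EncodedMatrix", "encode", "decode_counts"]

MISSING_CODE = -1


@dataclass
class EncodedMatrix:
    """X in {-1,0,1,2}^(M x N), rows = samples, columns = feature SNPs."""

    X: np.ndarray  # int8
    row_ids: list
    col_ids: list

    def __post_init__(self) -> None:
        if not np.isin(self.X, [-1, 0, 1, 2]).all():
            raise ValueError("encoded entries must be in {-1, 0, 1, 2}")

    @property
    def shape(self) -> tuple:
        return self.X.shape

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.X, columns=self.col_ids, index=self.row_ids).to_csv(
            path, sep="\t", index_label="sample_id"
        )


def encode(cohort: Cohort, features: FeatureSet) -> EncodedMatrix:
    """Build the model input for one feature set.

    The cohort stores minor-allele counts already; a column is re-polarized
    (0 <-> 2) when the pooled frequency of the stored allele exceeds 0.5,
    or on an exact 0.5 tie when the stored allele label sorts after its
    partner, so that every column counts the designated minor allele.
    """
    idx = features.variant_indices
    n_var = cohort.n_variants
    if (idx < 0).any() or (idx >= n_var).any():
        bad = features.table["rsid"].iloc[int(np.argmax((idx < 0) | (idx >= n_var)))]
        raise KeyError(f"feature variant {bad} absent from cohort")
    cohort_rsids = cohort.variants["rsid"].to_numpy()
    for k, rsid in enumerate(features.rsids):
        if cohort_rsids[idx[k]] != rsid:
            raise KeyError(f"feature variant {rsid} absent from cohort")

    G = cohort.genotypes[:, idx]
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(G, axis=0) / 2.0
    minor = cohort.variants["minor_allele"].to_numpy()[idx]
    major = cohort.variants["major_allele"].to_numpy()[idx]
    tie_flip = (freq == 0.5) & (minor > major)
    flip = (freq > 0.5) | tie_flip

    X = G.copy()
    X[:, flip] = 2.0 - X[:, flip]
    X = np.where(np.isnan(X), MISSING_CODE, X).astype(np.int8)
    return EncodedMatrix(
        X=X,
        row_ids=list(cohort.samples["sample_id"]),
        col_ids=list(features.rsids),
    )


def decode_counts(encoded: EncodedMatrix) -> pd.DataFrame:
    """Per-SNP genotype counts {0, 1, 2, missing}; used by QC checks."""
    X = encoded.X
    out = pd.DataFrame(
        {
            "rsid": encoded.col_ids,
            "n0": (X == 0).sum(axis=0),
            "n1": (X == 1).sum(axis=0),
            "n2": (X == 2).sum(axis=0),
            "n_missing": (X == MISSING_CODE).sum(axis=0),
        }
    )
    called = out["n1"] + 2 * out["n2"]
    denom = 2 * (out["n0"] + out["n1"] + out["n2"])
    out["maf"] = np.where(denom > 0, called / denom.replace(0, 1), np.nan)
    return out
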