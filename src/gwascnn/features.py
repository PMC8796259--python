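"""Summary-statistics-driven SNP selection.

External GWAS summary statistics are mapped onto the study cohort's
variants (match key: rsid), effect alleles are harmonized to the cohort
minor allele, and the model's input SNP sets are formed by p-value
thresholding — from genome-wide significance (p < 5e-8) up to p < 1e-3 —
plus the non-significant negative-control rule p >= 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_RULE",
    "STANDARD_THRESHOLDS",
    "FeatureSet",
    "harmonize",
    "select_features",
]

#: Sentinel threshold for the non-significant control subset (p >= 0.99).
CONTROL_RULE = "p>=0.99"

#: The threshold grid used for the main performance panels.
STANDARD_THRESHOLDS = (5.0e-8, 1.0e-6, 1.0e-5, 1.0e-4, 1.0e-3)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved without frequencies."""
    return _COMPLEMENT.get(a1) == a2


@dataclass
class FeatureSet:
    """An ordered SNP subset defined by a p-value rule.

    ``variant_indices`` are positions into the cohort's variant table,
    strictly increasing in (chrom, bp); ``table`` carries rsid, chrom,
    bp, harmonized OR and p per retained SNP.
    """

    threshold: Union[float, str]
    variant_indices: np.ndarray
    table: pd.DataFrame

    @property
    def rsids(self) -> list:
        return list(self.table["rsid"])

    def __len__(self) -> int:
        return len(self.variant_indices)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def harmonize(cohort, stats: pd.DataFrame) -> pd.DataFrame:
    """Align external summary statistics to the cohort's minor alleles.

    Per shared rsid: if the stats effect allele equals the cohort minor
    allele the OR is kept ("match"); if it equals the cohort major
    allele the OR is inverted so all effects are per cohort minor allele
    ("flipped"); strand-ambiguous pairs (A/T, C/G) are dropped, as are
    rsids absent from the cohort and allele pairs that disagree with the
    cohort's.  Returns the harmonized table with a ``flag`` column and
    0-based ``cohort_index``; dropped rows keep their flag but have
    index -1.
    """
    if len(stats) == 0 or cohort.n_variants == 0:
        raise ValueError("harmonize requires non-empty cohort and summary stats")
    cv = cohort.variants
    lookup = {
        r: (i, mi, ma)
        for i, (r, mi, ma) in enumerate(
            zip(cv["rsid"], cv["minor_allele"], cv["major_allele"])
        )
    }
    flags = []
    idx = []
    orr = stats["odds_ratio"].to_numpy(dtype=float).copy()
    for k, row in enumerate(
        zip(stats["rsid"], stats["effect_allele"], stats["other_allele"])
    ):
        rsid, ea, oa = row
        hit = lookup.get(rsid)
        if hit is None:
            flags.append("dropped_unmatched")
            idx.append(-1)
            continue
        if _is_ambiguous(ea, oa):
            flags.append("dropped_ambiguous")
            idx.append(-1)
            continue
        i, minor, major = hit
        if ea == minor and oa == major:
            flags.append("match")
            idx.append(i)
        elif ea == major and oa == minor:
            flags.append("flipped")
            orr[k] = 1.0 / orr[k]
            idx.append(i)
        else:
            flags.append("dropped_unmatched")
            idx.append(-1)
    out = stats.copy()
    out["odds_ratio"] = orr
    out["flag"] = flags
    out["cohort_index"] = idx
    if not (out["cohort_index"] >= 0).any():
        raise ValueError("no summary-statistics SNP could be matched to the cohort")
    return out


def select_features(
    harmonized: pd.DataFrame, threshold: Union[float, str]
) -> FeatureSet:
    """SNP set at one p-value rule, ordered by genomic coordinate.

    ``threshold`` is either a numeric cut-off (retain p < threshold) or
    :data:`CONTROL_RULE` (retain p >= 0.99, the non-significant control
    subset).  Raises if the selection is empty.
    """
    kept = harmonized[harmonized["cohort_index"] >= 0]
    if threshold == CONTROL_RULE:
        sel = kept[kept["p_value"] >= 0.99]
    else:
        t = float(threshold)
        sel = kept[kept["p_value"] < t]
    if len(sel) == 0:
        raise ValueError(f"no SNPs selected at threshold {threshold}")
    chrom_key = pd.to_numeric(sel["chrom"], errors="coerce").fillna(10**9)
    sel = sel.assign(_ck=chrom_key).sort_values(
        ["_ck", "chrom", "bp", "rsid"], kind="mergesort"
    )
    table = sel[
        ["rsid", "chrom", "bp", "effect_allele", "other_allele",
         "odds_ratio", "p_value", "flag"]
    ].reset_index(drop=True)
    return FeatureSet(
        threshold=threshold,
        variant_indices=sel["cohort_index"].to_numpy(dtype=int),
        table=table,
    )
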