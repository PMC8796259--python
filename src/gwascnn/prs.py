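"""Polygenic risk score baseline: LD clumping and weighted allele scoring.

Clumping is the standard greedy p-value-ordered pruning: candidates
below the p threshold are visited best-p first; each index SNP is
retained and removes every remaining candidate on the same chromosome
within +/- 250 kb whose squared genotype correlation with it exceeds
r^2 = 0.1 (both defaults configurable).  The LD reference is the
analysis cohort's own genotype matrix.  The score is the usual weighted
allele sum, PRS_m = sum_i w_i g_mi with w_i the harmonized log OR per
minor allele; missing genotypes contribute their expectation 2*MAF
(mean imputation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Cohort

__all__ = ["PRSModel", "clump", "score"]


@dataclass
class PRSModel:
    retained: pd.DataFrame  # rsid, chrom, bp, weight (log OR), p_value
    clump_r2: float
    clump_window_bp: int
    threshold: float


def _genotype_r2(G: np.ndarray, i: int, js: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of genotype codes, missing mean-imputed."""
    gi = G[:, i].copy()
    gi[np.isnan(gi)] = np.nanmean(gi)
    gi = gi - gi.mean()
    denom_i = (gi**2).sum()
    out = np.empty(js.size)
    for t, j in enumerate(js):
        gj = G[:, j].copy()
        gj[np.isnan(gj)] = np.nanmean(gj)
        gj = gj - gj.mean()
        denom_j = (gj**2).sum()
        if denom_i == 0.0 or denom_j == 0.0:
            out[t] = 0.0
        else:
            out[t] = (gi @ gj) ** 2 / (denom_i * denom_j)
    return out


def clump(
    harmonized: pd.DataFrame,
    cohort: Cohort,
    clump_r2: float = 0.1,
    clump_window_bp: int = 250_000,
    threshold: float = 1e-3,
) -> PRSModel:
    """Greedy p-ordered LD clumping against the cohort's genotypes.

    Ties in p are broken by (chrom, bp, rsid) so the greedy order — and
    therefore the result — is independent of input row order.
    """
    cand = harmonized[
        (harmonized["cohort_index"] >= 0) & (harmonized["p_value"] < threshold)
    ].copy()
    if len(cand) == 0:
        raise ValueError(f"no clumping candidates at threshold {threshold}")
    ck = pd.to_numeric(cand["chrom"], errors="coerce").fillna(10**9)
    cand = cand.assign(_ck=ck).sort_values(
        ["p_value", "_ck", "chrom", "bp", "rsid"], kind="mergesort"
    )

    G = cohort.genotypes
    idx = cand["cohort_index"].to_numpy(dtype=int)
    chrom = cand["chrom"].to_numpy()
    bp = cand["bp"].to_numpy(dtype=int)

    alive = np.ones(len(cand), dtype=bool)
    kept_rows = []
    for i in range(len(cand)):
        if not alive[i]:
            continue
        kept_rows.append(i)
        near = np.flatnonzero(
            alive
            & (chrom == chrom[i])
            & (np.abs(bp - bp[i]) <= clump_window_bp)
        )
        near = near[near != i]
        if near.size:
            r2 = _genotype_r2(G, idx[i], idx[near])
            alive[near[r2 > clump_r2]] = False
        alive[i] = False

    kept = cand.iloc[kept_rows]
    retained = pd.DataFrame(
        {
            "rsid": kept["rsid"].to_numpy(),
            "chrom": kept["chrom"].to_numpy(),
            "bp": kept["bp"].to_numpy(),
            "weight": np.log(kept["odds_ratio"].to_numpy(dtype=float)),
            "p_value": kept["p_value"].to_numpy(),
            "cohort_index": kept["cohort_index"].to_numpy(dtype=int),
        }
    )
    return PRSModel(
        retained=retained,
        clump_r2=clump_r2,
        clump_window_bp=clump_window_bp,
        threshold=threshold,
    )


def score(model: PRSModel, cohort: Cohort) -> pd.DataFrame:
    """Per-sample weighted allele sum over the retained SNPs."""
    rsid_to_col = {r: i for i, r in enumerate(cohort.variants["rsid"])}
    cols = []
    for r in model.retained["rsid"]:
        if r not in rsid_to_col:
            raise KeyError(f"retained SNP {r} missing from cohort")
        cols.append(rsid_to_col[r])
    G = cohort.genotypes[:, cols].copy()
    with np.errstate(invalid="ignore"):
        fill = np.nan_to_num(np.nanmean(G, axis=0))  # mean genotype = 2 * maf
    miss = np.isnan(G)
    G[miss] = np.broadcast_to(fill, G.shape)[miss]
    w = model.retained["weight"].to_numpy(dtype=float)
    prs = G @ w
    return pd.DataFrame(
        {
            "sample_id": cohort.samples["sample_id"],
            "score": prs,
            "status": cohort.samples["status"],
        }
    )
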