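"""Per-SNP case-control association scan.

For each variant a single-predictor logistic regression of status on
minor-allele count is fitted (missing calls excluded) and summarized as
the odds ratio exp(beta), its Wald 95% confidence interval and Wald
p-value.  Degenerate columns — monomorphic sites or complete separation,
where maximum likelihood diverges — fall back to the allelic 2x2
cross-product odds ratio (Haldane-Anscombe 0.5 correction when a cell is
empty) with a two-sided Fisher exact p-value.

The Newton-Raphson fit is vectorized across SNPs: every SNP shares the
same response vector and differs only in its predictor column and
missingness mask, so the 2-parameter score and information can be
accumulated for all SNPs at once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .simulate import Cohort

__all__ = ["scan", "manhattan_table"]

_Z975 = 1.959963984540054
# |log OR| beyond this is numerically divergent for genotype data and is
# treated as separation.
_BETA_DIVERGED = 15.0


def _fisher_fallback(
    g: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """Allelic 2x2 OR/CI/p for a degenerate genotype column.

    Cells are minor/major allele counts in cases and controls; the 0.5
    continuity correction is applied to the OR and its Woolf CI only
    when some cell is zero.  The p-value is Fisher's exact test on the
    uncorrected table.
    """
    ok = ~np.isnan(g)
    gc = g[ok & (y == 1)]
    gn = g[ok & (y == 0)]
    a = float(gc.sum())            # case minor alleles
    b = float(2 * gc.size - a)     # case major alleles
    c = float(gn.sum())            # control minor alleles
    d = float(2 * gn.size - c)     # control major alleles
    table = np.array([[a, b], [c, d]])
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = orr * np.exp(-_Z975 * se)
    hi = orr * np.exp(_Z975 * se)
    p = float(sps.fisher_exact(np.round(table).astype(int), alternative="two-sided")[1])
    return orr, lo, hi, max(p, np.finfo(float).tiny)


def _vectorized_logistic(
    G: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-8,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit logit(P(y=1)) = b0 + b1*g independently for every column of G.

    Returns (b1, se_b1, converged).  NaN predictor entries are excluded
    per SNP by zero-weighting.  Columns are processed in chunks to keep
    the Newton temporaries bounded at genome-panel widths.
    """
    n, p = G.shape
    if p > chunk:
        parts = [
            _vectorized_logistic(G[:, s : s + chunk], y, max_iter, tol, chunk)
            for s in range(0, p, chunk)
        ]
        return tuple(np.concatenate([q[i] for q in parts]) for i in range(3))
    ok = ~np.isnan(G)
    Gz = np.where(ok, G, 0.0)
    yv = y[:, None].astype(float)

    ybar = (yv * ok).sum(0) / ok.sum(0)
    b0 = np.log(ybar / (1 - ybar))
    b1 = np.zeros(p)
    converged = np.zeros(p, dtype=bool)
    for _ in range(max_iter):
        eta = b0 + Gz * b1
        mu = expit(eta)
        w = np.where(ok, mu * (1 - mu), 0.0)
        r = np.where(ok, yv - mu, 0.0)
        u0 = r.sum(0)
        u1 = (r * Gz).sum(0)
        i00 = w.sum(0)
        i01 = (w * Gz).sum(0)
        i11 = (w * Gz * Gz).sum(0)
        det = i00 * i11 - i01 * i01
        with np.errstate(divide="ignore", invalid="ignore"):
            d0 = (i11 * u0 - i01 * u1) / det
            d1 = (i00 * u1 - i01 * u0) / det
        bad = ~np.isfinite(d0) | ~np.isfinite(d1)
        d0 = np.where(bad, 0.0, d0)
        d1 = np.where(bad, 0.0, d1)
        b0 = b0 + d0
        b1 = b1 + d1
        converged = np.maximum(np.abs(d0), np.abs(d1)) < tol
        if converged.all():
            break
    eta = b0 + Gz * b1
    mu = expit(eta)
    w = np.where(ok, mu * (1 - mu), 0.0)
    i00 = w.sum(0)
    i01 = (w * Gz).sum(0)
    i11 = (w * Gz * Gz).sum(0)
    det = i00 * i11 - i01 * i01
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(i00 / det)
    return b1, se, converged & np.isfinite(se) & (np.abs(b1) < _BETA_DIVERGED)


def scan(cohort: Cohort, min_nonmissing: int = 10) -> pd.DataFrame:
    """Association statistics for every variant in the cohort.

    Returns a DataFrame with columns rsid, chrom, bp, minor_allele,
    major_allele, maf, odds_ratio, ci_low, ci_high, p_value, method
    ("wald" or "fisher" for the degenerate fallback), in the cohort's
    variant order.
    """
    y = cohort.status
    if len(np.unique(y)) < 2:
        raise ValueError("association scan requires both cases and controls")
    G = cohort.genotypes
    ok = ~np.isnan(G)
    n_ok = ok.sum(0)
    if (n_ok < min_nonmissing).any():
        bad = cohort.variants["rsid"].to_numpy()[n_ok < min_nonmissing][0]
        raise ValueError(
            f"variant {bad} has fewer than {min_nonmissing} non-missing calls"
        )

    with np.errstate(invalid="ignore"):
        col_var = np.nanvar(G, axis=0)
    monomorphic = col_var == 0.0

    b1, se, converged = _vectorized_logistic(G, y)
    use_fallback = monomorphic | ~converged

    orr = np.exp(b1)
    lo = np.exp(b1 - _Z975 * se)
    hi = np.exp(b1 + _Z975 * se)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se
    pv = 2.0 * sps.norm.sf(np.abs(z))
    pv = np.clip(pv, np.finfo(float).tiny, 1.0)

    for j in np.flatnonzero(use_fallback):
        orr[j], lo[j], hi[j], pv[j] = _fisher_fallback(G[:, j], y)

    out = cohort.variants[
        ["rsid", "chrom", "bp", "minor_allele", "major_allele", "maf"]
    ].copy()
    out["odds_ratio"] = orr
    out["ci_low"] = lo
    out["ci_high"] = hi
    out["p_value"] = pv
    out["method"] = np.where(use_fallback, "fisher", "wald")
    return out


def manhattan_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (chrom, bp, -log10 p) table in the input's order."""
    if len(stats) == 0:
        raise ValueError("empty association table")
    out = stats[["rsid", "chrom", "bp"]].copy()
    out["neg_log10_p"] = -np.log10(stats["p_value"].to_numpy())
    return out
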