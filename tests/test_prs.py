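"""LD clumping and polygenic-score computation against hand oracles."""

import numpy as np
import pandas as pd
import pytest

from gwascnn import clump, score
from conftest import make_cohort_from_matrix


def correlated_pair(rng, n, r, maf=0.3):
    """Two genotype columns with approximate correlation r."""
    g1 = rng.binomial(2, maf, n).astype(float)
    swap = rng.random(n) > abs(r)
    g2 = np.where(swap, rng.binomial(2, maf, n), g1)
    return g1, g2


def make_harmonized(cohort, p_values, odds_ratios=None):
    v = cohort.variants
    n = len(v)
    return pd.DataFrame(
        {
            "rsid": v["rsid"].to_numpy(),
            "chrom": v["chrom"].to_numpy(),
            "bp": v["bp"].to_numpy(),
            "effect_allele": v["minor_allele"].to_numpy(),
            "other_allele": v["major_allele"].to_numpy(),
            "odds_ratio": odds_ratios if odds_ratios is not None else [1.5] * n,
            "p_value": p_values,
            "flag": ["match"] * n,
            "cohort_index": np.arange(n),
        }
    )


def test_greedy_clump_hand_oracle():
    """3 SNPs within the window, p = 1e-10/1e-8/1e-3, r2(1,2) high and
    SNP3 uncorrelated: retained = {SNP1, SNP3}."""
    rng = np.random.default_rng(0)
    n = 3000
    g1 = rng.binomial(2, 0.3, n).astype(float)
    g2 = g1.copy()
    flip = rng.random(n) < 0.1
    g2[flip] = rng.binomial(2, 0.3, flip.sum())  # r2(1,2) ~ 0.8
    g3 = rng.binomial(2, 0.3, n).astype(float)   # independent
    coh = make_cohort_from_matrix(
        np.column_stack([g1, g2, g3]), bp=[10_000, 20_000, 30_000]
    )
    h = make_harmonized(coh, [1e-10, 1e-8, 1e-3])
    model = clump(h, coh, clump_r2=0.1, clump_window_bp=250_000, threshold=0.05)
    assert list(model.retained["rsid"]) == ["rs0", "rs2"]


def test_window_rule_spares_distant_duplicates():
    """Perfectly correlated SNPs 300 kb apart are both retained."""
    rng = np.random.default_rng(1)
    g = rng.binomial(2, 0.4, 500).astype(float)
    coh = make_cohort_from_matrix(
        np.column_stack([g, g]), bp=[100_000, 400_000]
    )
    h = make_harmonized(coh, [1e-8, 1e-6])
    model = clump(h, coh, clump_window_bp=250_000, threshold=0.05)
    assert len(model.retained) == 2


def test_different_chromosomes_never_clumped():
    rng = np.random.default_rng(2)
    g = rng.binomial(2, 0.4, 500).astype(float)
    coh = make_cohort_from_matrix(
        np.column_stack([g, g]), chrom=["1", "2"], bp=[100_000, 100_500]
    )
    h = make_harmonized(coh, [1e-8, 1e-6])
    assert len(clump(h, coh, threshold=0.05).retained) == 2


def test_uncorrelated_candidates_all_retained():
    rng = np.random.default_rng(3)
    G = rng.binomial(2, 0.3, (2000, 8)).astype(float)
    coh = make_cohort_from_matrix(G, bp=np.arange(8) * 1000 + 1000)
    h = make_harmonized(coh, np.linspace(1e-9, 1e-4, 8))
    assert len(clump(h, coh, threshold=0.05).retained) == 8


def test_empty_candidate_set_rejected(small_cohort):
    h = make_harmonized(small_cohort, [0.9] * small_cohort.n_variants)
    with pytest.raises(ValueError, match="1e-08"):
        clump(h, small_cohort, threshold=1e-8)


def test_row_order_invariance():
    rng = np.random.default_rng(4)
    G = rng.binomial(2, 0.3, (1500, 12)).astype(float)
    coh = make_cohort_from_matrix(G, bp=np.arange(12) * 2000 + 1000)
    p = rng.uniform(1e-9, 1e-3, 12)
    h = make_harmonized(coh, p)
    a = clump(h, coh, threshold=0.05).retained["rsid"]
    shuffled = h.sample(frac=1.0, random_state=5).reset_index(drop=True)
    b = clump(shuffled, coh, threshold=0.05).retained["rsid"]
    assert list(a) == list(b)


def test_greedy_result_verified_by_exhaustive_constraint_check():
    """On a <= 25-SNP instance the retained set satisfies every pairwise
    constraint and each removal is justified by a better-p retained SNP."""
    rng = np.random.default_rng(6)
    n, p = 2500, 20
    G = np.empty((n, p))
    for j in range(p):
        if j % 3 == 0 or j == 0:
            G[:, j] = rng.binomial(2, 0.3, n)
        else:  # correlate with previous column
            base = G[:, j - 1]
            keep = rng.random(n) < 0.85
            G[:, j] = np.where(keep, base, rng.binomial(2, 0.3, n))
    coh = make_cohort_from_matrix(G, bp=np.arange(p) * 5000 + 1000)
    pvals = rng.uniform(1e-10, 1e-3, p)
    h = make_harmonized(coh, pvals)
    model = clump(h, coh, clump_r2=0.1, clump_window_bp=250_000, threshold=0.05)
    kept = set(model.retained["rsid"])

    def r2(i, j):
        return np.corrcoef(G[:, i], G[:, j])[0, 1] ** 2

    idx = {r: i for i, r in enumerate(coh.variants["rsid"])}
    bp = coh.variants["bp"].to_numpy()
    kept_idx = sorted(idx[r] for r in kept)
    # no retained pair violates the r2/window constraint
    for a_i in kept_idx:
        for b_i in kept_idx:
            if a_i < b_i and abs(bp[a_i] - bp[b_i]) <= 250_000:
                assert r2(a_i, b_i) <= 0.1
    # every removed candidate conflicts with a retained SNP of better p
    for j in range(p):
        if coh.variants["rsid"][j] in kept:
            continue
        conflicts = [
            k for k in kept_idx
            if abs(bp[k] - bp[j]) <= 250_000
            and r2(k, j) > 0.1
            and pvals[k] < pvals[j]
        ]
        assert conflicts, f"SNP {j} removed without justification"


def test_score_closed_form():
    G = np.array([[0.0], [1.0], [2.0]])
    coh = make_cohort_from_matrix(G, status=[1, 0, 0])
    h = make_harmonized(coh, [1e-9], odds_ratios=[2.0])
    model = clump(h, coh, threshold=0.05)
    s = score(model, coh)["score"].to_numpy()
    np.testing.assert_allclose(s, [0.0, np.log(2), 2 * np.log(2)], rtol=1e-12)


def test_zero_weights_zero_scores():
    G = np.array([[0.0, 1], [1, 2], [2, 0]])
    coh = make_cohort_from_matrix(G)
    h = make_harmonized(coh, [1e-9, 1e-8], odds_ratios=[1.0, 1.0])
    s = score(clump(h, coh, threshold=0.05), coh)["score"]
    np.testing.assert_allclose(s, 0.0)


def test_missing_genotype_mean_imputed():
    G = np.array([[0.0], [2.0], [np.nan]])
    coh = make_cohort_from_matrix(G)
    h = make_harmonized(coh, [1e-9], odds_ratios=[np.e])  # weight = 1
    s = score(clump(h, coh, threshold=0.05), coh)["score"].to_numpy()
    np.testing.assert_allclose(s, [0.0, 2.0, 1.0])  # 2*maf = 1


def test_allele_flip_preserves_score_differences():
    rng = np.random.default_rng(7)
    G = rng.binomial(2, 0.4, (50, 2)).astype(float)
    coh = make_cohort_from_matrix(G)
    h = make_harmonized(coh, [1e-9, 1e-8], odds_ratios=[2.0, 0.5])
    s1 = score(clump(h, coh, threshold=0.05), coh)["score"].to_numpy()
    flipped = make_cohort_from_matrix(np.column_stack([2.0 - G[:, 0], G[:, 1]]))
    h2 = make_harmonized(flipped, [1e-9, 1e-8], odds_ratios=[0.5, 0.5])
    s2 = score(clump(h2, flipped, threshold=0.05), flipped)["score"].to_numpy()
    np.testing.assert_allclose(s1 - s1[0], s2 - s2[0], atol=1e-12)


def test_prs_discrimination_grows_with_liability_variance():
    """3-point sweep: more genetic variance, better PRS separation."""
    from gwascnn import default_config, harmonize, simulate_cohort, \
        simulate_summary_stats

    aucs = []
    for scale in (0.3, 1.0, 2.0):
        lo, hi = np.log(1.3) * scale, np.log(2.0) * scale
        cfg = default_config(
            n_cases=250, n_controls=1000, n_snps=120, n_causal=8,
            ld_block_r=0.0, missing_rate=0.0, seed=42,
            abs_log_or_range=(lo, hi),
        )
        coh = simulate_cohort(cfg)
        stats = simulate_summary_stats(cfg, 2000, 2000, seed=43)
        h = harmonize(coh, stats)
        model = clump(h, coh, threshold=0.05)
        s = score(model, coh)
        from gwascnn.evaluation import auc_mann_whitney

        aucs.append(auc_mann_whitney(s["score"], s["status"]))
    assert aucs[0] > 0.5
    assert aucs[0] < aucs[1] < aucs[2]
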