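"""Generator calibration: Hardy-Weinberg, effect direction, LD copula,
determinism, and the reference summary-statistics simulator."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.special import ndtri

from gwascnn import (
    SimulationConfig,
    VariantSpec,
    default_config,
    simulate_cohort,
    simulate_summary_stats,
)
from gwascnn.association import scan
from gwascnn.io import write_summary_stats


def null_config(n_snps=20, n_cases=1000, n_controls=4000, seed=3, **kw):
    specs = tuple(
        VariantSpec(rsid=f"rs{i}", chrom="1", bp=1000 + 100 * i,
                    maf=0.1 + 0.4 * i / max(n_snps - 1, 1), log_or=0.0)
        for i in range(n_snps)
    )
    return SimulationConfig(
        n_cases=n_cases, n_controls=n_controls, variants=specs,
        missing_rate=0.0, seed=seed, **kw,
    )


def test_null_model_case_control_frequency_symmetry():
    """With every log OR = 0, case and control MAFs agree up to binomial noise."""
    cfg = null_config(n_snps=30, n_cases=2000, n_controls=2000)
    coh = simulate_cohort(cfg)
    y = coh.status
    f_case = coh.genotypes[y == 1].mean(0) / 2
    f_ctrl = coh.genotypes[y == 0].mean(0) / 2
    q = np.array([v.maf for v in cfg.variants])
    se = np.sqrt(q * (1 - q) * (1 / (2 * 2000) + 1 / (2 * 2000)))
    assert np.all(np.abs(f_case - f_ctrl) < 4.5 * se)


def test_hardy_weinberg_genotype_frequencies():
    """Null, LD-free SNPs match (1-q)^2 / 2q(1-q) / q^2 within 3 binomial SDs."""
    cfg = null_config(n_snps=20, n_cases=1000, n_controls=4000)
    coh = simulate_cohort(cfg)
    n = coh.n_samples
    q = np.array([v.maf for v in cfg.variants])
    expected = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    for g in (0, 1, 2):
        obs = (coh.genotypes == g).mean(0)
        sd = np.sqrt(expected[g] * (1 - expected[g]) / n)
        assert np.all(np.abs(obs - expected[g]) < 3.5 * sd)


def test_effect_direction():
    """A positive log OR raises the case minor-allele frequency; negative lowers it."""
    specs = (
        VariantSpec("rsA", "1", 1000, maf=0.3, log_or=np.log(1.8)),
        VariantSpec("rsB", "1", 2000, maf=0.3, log_or=np.log(0.55)),
    )
    cfg = SimulationConfig(n_cases=1500, n_controls=1500, variants=specs,
                           missing_rate=0.0, seed=5)
    coh = simulate_cohort(cfg)
    y = coh.status
    diff = coh.genotypes[y == 1].mean(0) - coh.genotypes[y == 0].mean(0)
    assert diff[0] > 0 and diff[1] < 0


def test_determinism_same_config_same_cohort(small_config):
    a = simulate_cohort(small_config)
    b = simulate_cohort(small_config)
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    assert a.samples.equals(b.samples)


def test_ld_copula_matches_monte_carlo_oracle():
    """Observed genotype r^2 in a 2-SNP block tracks a brute-force draw
    of the same latent-Gaussian copula (10^6 samples)."""
    r, maf1, maf2 = 0.8, 0.3, 0.4
    specs = (
        VariantSpec("rs1", "1", 1000, maf=maf1, block_id=0),
        VariantSpec("rs2", "1", 1100, maf=maf2, block_id=0),
    )
    cfg = SimulationConfig(n_cases=1000, n_controls=4000, variants=specs,
                           ld_block_r=r, missing_rate=0.0, seed=11)
    coh = simulate_cohort(cfg)
    obs_r2 = np.corrcoef(coh.genotypes.T)[0, 1] ** 2

    # independent oracle: equicorrelated bivariate normal + HW thresholds
    rng = np.random.default_rng(2024)
    n = 1_000_000
    c = rng.standard_normal(n)
    z1 = np.sqrt(r) * c + np.sqrt(1 - r) * rng.standard_normal(n)
    z2 = np.sqrt(r) * c + np.sqrt(1 - r) * rng.standard_normal(n)

    def geno(z, q):
        return ((z > ndtri((1 - q) ** 2)).astype(float)
                + (z > ndtri(1 - q**2)))

    oracle_r2 = np.corrcoef(geno(z1, maf1), geno(z2, maf2))[0, 1] ** 2
    assert abs(obs_r2 - oracle_r2) < 0.1


def test_association_recovers_planted_protective_odds_ratio():
    """A strongly protective common SNP (MAF 0.476, OR 0.42) is recovered
    by the association scan within its 95% CI at study-like n."""
    specs = (VariantSpec("rs_target", "4", 111_711_041, maf=0.476,
                         log_or=float(np.log(0.42))),)
    cfg = SimulationConfig(n_cases=872, n_controls=5486, variants=specs,
                           missing_rate=0.0, seed=0)
    coh = simulate_cohort(cfg)
    st = scan(coh).iloc[0]
    assert st["ci_low"] <= 0.42 <= st["ci_high"]
    assert st["p_value"] < 1e-10


def test_quota_unreachable_reports_prevalence():
    cfg = replace(null_config(n_snps=2, n_cases=50, n_controls=10),
                  baseline_log_odds=-40.0)
    with pytest.raises(RuntimeError, match="prevalence"):
        simulate_cohort(cfg)


@pytest.mark.parametrize(
    "bad",
    [
        dict(maf=0.7),
        dict(maf=0.0),
        dict(bp=0),
    ],
)
def test_invalid_variant_rejected(bad):
    kw = dict(rsid="rs1", chrom="1", bp=100, maf=0.2)
    kw.update(bad)
    with pytest.raises(ValueError):
        VariantSpec(**kw).validate()


def test_invalid_config_rejected():
    specs = (VariantSpec("rs1", "1", 100, 0.2),)
    with pytest.raises(ValueError):
        SimulationConfig(n_cases=0, n_controls=10, variants=specs).validate()
    with pytest.raises(ValueError):
        SimulationConfig(n_cases=5, n_controls=10, variants=specs,
                         missing_rate=1.0).validate()
    out_of_order = (VariantSpec("rs1", "1", 200, 0.2),
                    VariantSpec("rs2", "1", 100, 0.2))
    with pytest.raises(ValueError, match="increasing"):
        SimulationConfig(n_cases=5, n_controls=10,
                         variants=out_of_order).validate()


def test_null_summary_stats_have_uniform_tail():
    """All-null panel: about 1% of reference p-values land at p >= 0.99."""
    cfg = null_config(n_snps=2000, n_cases=10, n_controls=10)
    stats = simulate_summary_stats(cfg, 1000, 1000, seed=21)
    frac = (stats["p_value"] >= 0.99).mean()
    se = np.sqrt(0.01 * 0.99 / 2000)
    assert abs(frac - 0.01) < 4 * se


def test_planted_strong_risk_snp_reaches_genome_wide_significance():
    """An OR ~2 common SNP hits p < 5e-8 in a large reference scan."""
    specs = (VariantSpec("rs_risk", "4", 111_689_666, maf=0.423,
                         log_or=float(np.log(2.01))),)
    cfg = SimulationConfig(n_cases=10, n_controls=10, variants=specs,
                           missing_rate=0.0, seed=1)
    stats = simulate_summary_stats(cfg, 3000, 3000, seed=2)
    assert stats["p_value"].iloc[0] < 5e-8


def test_summary_stats_byte_identical_under_fixed_seed(tmp_path, small_config):
    paths = []
    for i in (0, 1):
        stats = simulate_summary_stats(small_config, 400, 400, seed=9)
        p = tmp_path / f"stats{i}.tsv"
        write_summary_stats(stats, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_missingness_rate():
    cfg = replace(null_config(n_snps=50, n_cases=500, n_controls=500),
                  missing_rate=0.05)
    coh = simulate_cohort(cfg)
    frac = np.isnan(coh.genotypes).mean()
    assert abs(frac - 0.05) < 0.01


def test_covariate_imbalance_mirrors_study_defaults(small_cohort):
    s = small_cohort.samples
    case = s[s.status == 1]
    ctrl = s[s.status == 0]
    assert case["age"].mean() < ctrl["age"].mean()
    assert (case["sex"] == "M").mean() > (ctrl["sex"] == "M").mean()
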