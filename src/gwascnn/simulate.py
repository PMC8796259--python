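"""Synthetic case-control genotype cohorts with known ground truth.

Generates cohorts whose shape mirrors a typical single-population
case-control GWAS: a few hundred to a few thousand cases against several
thousand controls, O(10^3-10^4) biallelic SNPs, a handful of causal loci
with per-minor-allele odds ratios, block-wise linkage disequilibrium,
missing genotype calls, and age/sex covariates that differ between the
two groups.  Every downstream stage (feature selection, encoding, the
CNN classifier, saliency, PRS, the negative controls) is tested against
these cohorts because real clinical genotype data are access-restricted.

Model
-----
Genotypes are drawn per LD block from a latent-Gaussian copula: each SNP
has two thresholds placed at its Hardy-Weinberg genotype quantiles, and
SNPs sharing a block draw their latent normals with pairwise correlation
``ld_block_r``.  Disease status is prospective-logistic,

    P(case | g) = sigmoid(baseline_log_odds + sum_i log_or_i * g_i),

with g the minor-allele count, and the fixed case/control quotas are
filled by rejection sampling conditional on status (the study design is
retrospective case-control).  Missing calls are missing-completely-at-
random.  Covariates are generated per status group and never feed back
into the genotype model; they exist for propensity-score matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

__all__ = [
    "VariantSpec",
    "CovariateModel",
    "SimulationConfig",
    "Cohort",
    "simulate_cohort",
    "simulate_summary_stats",
    "default_variant_specs",
    "default_config",
]

# Allele pairs assigned to generated variants.  A/T and C/G pairs are
# strand-ambiguous and excluded by default so that harmonization against
# external summary statistics retains the variant.
_UNAMBIGUOUS_PAIRS = [
    ("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
    ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T"),
]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class VariantSpec:
    """Ground-truth description of one simulated SNP."""

    rsid: str
    chrom: str
    bp: int
    maf: float
    log_or: float = 0.0
    block_id: Optional[int] = None
    minor_allele: str = "A"
    major_allele: str = "G"

    def validate(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(
                f"{self.rsid}: maf must be in (0, 0.5], got {self.maf}"
            )
        if self.bp < 1:
            raise ValueError(f"{self.rsid}: bp must be >= 1, got {self.bp}")
        if self.minor_allele == self.major_allele:
            raise ValueError(f"{self.rsid}: alleles must differ")


@dataclass(frozen=True)
class CovariateModel:
    """Age (normal per group) and sex (Bernoulli male per group).

    Defaults follow the demographic imbalance of an early-onset AF
    ablation cohort versus population controls: cases younger and
    predominantly male.
    """

    age_mean_case: float = 50.4
    age_sd_case: float = 7.9
    age_mean_control: float = 55.6
    age_sd_control: float = 8.6
    p_male_case: float = 0.805
    p_male_control: float = 0.455


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int
    n_controls: int
    variants: tuple  # tuple[VariantSpec, ...]
    baseline_log_odds: Optional[float] = None  # None -> calibrated to target_prevalence
    target_prevalence: float = 0.05
    ld_block_r: float = 0.0
    missing_rate: float = 0.01
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not (0.0 <= self.ld_block_r < 1.0):
            raise ValueError(f"ld_block_r must be in [0, 1), got {self.ld_block_r}")
        if len(self.variants) == 0:
            raise ValueError("at least one variant required")
        seen: dict = {}
        for v in self.variants:
            v.validate()
            if v.rsid in seen:
                raise ValueError(f"duplicate rsid {v.rsid}")
            seen[v.rsid] = True
        # positions strictly increasing within a chromosome
        by_chrom: dict = {}
        for v in self.variants:
            prev = by_chrom.get(v.chrom)
            if prev is not None and v.bp <= prev:
                raise ValueError(
                    f"positions not strictly increasing on chrom {v.chrom} at {v.rsid}"
                )
            by_chrom[v.chrom] = v.bp

    # -- flat key-value (JSON) serialization ------------------------------
    def to_json(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = json.load(fh)
        doc["variants"] = tuple(VariantSpec(**v) for v in doc["variants"])
        doc["covariate_model"] = CovariateModel(**doc["covariate_model"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg


@dataclass
class Cohort:
    """Samples x variants genotype cohort.

    ``samples``: DataFrame with columns sample_id, status (1 case /
    0 control), registration_index (1-based generation order), age, sex
    ("M"/"F").  ``variants``: DataFrame with columns rsid, chrom, bp,
    minor_allele, major_allele, maf (observed).  ``genotypes``: float
    array of minor-allele counts {0,1,2} with NaN for missing calls.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            bad = vals[~np.isin(vals, [0.0, 1.0, 2.0])][0]
            raise ValueError(f"genotype entries must be in {{0,1,2,NaN}}; found {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def status(self) -> np.ndarray:
        return self.samples["status"].to_numpy(dtype=int)

    def observed_maf(self) -> np.ndarray:
        """Frequency of the designated minor allele from the matrix."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0


# ---------------------------------------------------------------------------
# genotype drawing


def _hw_thresholds(maf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent-normal cut points at Hardy-Weinberg genotype quantiles."""
    q = np.asarray(maf, dtype=float)
    p0 = (1.0 - q) ** 2
    p01 = 1.0 - q**2
    return ndtri(p0), ndtri(p01)


def _draw_genotypes(
    rng: np.random.Generator,
    n: int,
    maf: np.ndarray,
    block_ids: np.ndarray,
    block_r: float,
) -> np.ndarray:
    """n x p minor-allele count matrix from the latent-Gaussian copula."""
    p = maf.size
    z = rng.standard_normal((n, p))
    if block_r > 0.0:
        sr, se = np.sqrt(block_r), np.sqrt(1.0 - block_r)
        for b in np.unique(block_ids):
            if b < 0:  # -1 encodes "no block"
                continue
            idx = np.flatnonzero(block_ids == b)
            if idx.size < 2:
                continue
            common = rng.standard_normal((n, 1))
            z[:, idx] = sr * common + se * z[:, idx]
    t0, t1 = _hw_thresholds(maf)
    return (z > t0).astype(np.float64) + (z > t1)


def _calibrate_intercept(
    config: SimulationConfig, rng: np.random.Generator, n_mc: int = 4000
) -> float:
    """Bisection for the intercept giving the target population prevalence."""
    maf = np.array([v.maf for v in config.variants])
    blocks = np.array(
        [-1 if v.block_id is None else v.block_id for v in config.variants]
    )
    beta = np.array([v.log_or for v in config.variants])
    g = _draw_genotypes(rng, n_mc, maf, blocks, config.ld_block_r)
    eta = g @ beta
    lo, hi = -30.0, 10.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta).mean() < config.target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a case-control cohort by rejection sampling on disease status.

    Raises ``RuntimeError`` naming the achieved prevalence if either
    quota cannot be filled within a bounded number of draws.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    maf = np.array([v.maf for v in config.variants])
    blocks = np.array(
        [-1 if v.block_id is None else v.block_id for v in config.variants]
    )
    beta = np.array([v.log_or for v in config.variants])

    b0 = config.baseline_log_odds
    if b0 is None:
        b0 = _calibrate_intercept(config, np.random.default_rng(config.seed + 1))

    n_cases, n_controls = config.n_cases, config.n_controls
    want = n_cases + n_controls
    geno_rows: list[np.ndarray] = []
    status_rows: list[int] = []
    got_cases = got_controls = 0
    drawn = 0
    max_draws = 250 * want + 100_000
    batch = max(2048, want // 4)
    while got_cases < n_cases or got_controls < n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                "case/control quota unreachable: after "
                f"{drawn} draws achieved prevalence "
                f"{got_cases / max(drawn, 1):.4g} "
                f"(need {n_cases} cases, have {got_cases}; "
                f"need {n_controls} controls, have {got_controls}); "
                "the baseline_log_odds is likely pathological"
            )
        g = _draw_genotypes(rng, batch, maf, blocks, config.ld_block_r)
        pr = expit(b0 + g @ beta)
        s = (rng.random(batch) < pr).astype(int)
        drawn += batch
        for i in range(batch):
            if s[i] == 1 and got_cases < n_cases:
                got_cases += 1
            elif s[i] == 0 and got_controls < n_controls:
                got_controls += 1
            else:
                continue
            geno_rows.append(g[i])
            status_rows.append(s[i])
            if got_cases == n_cases and got_controls == n_controls:
                break

    genotypes = np.asarray(geno_rows)
    status = np.asarray(status_rows)

    if config.missing_rate > 0.0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes = genotypes.astype(float)
        genotypes[miss] = np.nan

    cm = config.covariate_model
    is_case = status == 1
    age = np.where(
        is_case,
        rng.normal(cm.age_mean_case, cm.age_sd_case, want),
        rng.normal(cm.age_mean_control, cm.age_sd_control, want),
    )
    p_male = np.where(is_case, cm.p_male_case, cm.p_male_control)
    sex = np.where(rng.random(want) < p_male, "M", "F")

    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:06d}" for i in range(want)],
            "status": status,
            "registration_index": np.arange(1, want + 1),
            "age": np.round(age, 2),
            "sex": sex,
        }
    )
    variants = pd.DataFrame(
        {
            "rsid": [v.rsid for v in config.variants],
            "chrom": [v.chrom for v in config.variants],
            "bp": [v.bp for v in config.variants],
            "minor_allele": [v.minor_allele for v in config.variants],
            "major_allele": [v.major_allele for v in config.variants],
        }
    )
    with np.errstate(invalid="ignore"):
        variants["maf"] = np.nanmean(genotypes, axis=0) / 2.0
    return Cohort(samples=samples, variants=variants, genotypes=genotypes)


def simulate_summary_stats(
    config: SimulationConfig,
    n_ref_cases: int,
    n_ref_controls: int,
    seed: int,
    source_label: str = "simulated reference GWAS",
) -> pd.DataFrame:
    """Association results from an independent reference cohort.

    Simulates a second cohort from the same variant specs (no shared
    samples), runs the per-SNP logistic scan, and returns a summary-
    statistics table (rsid, chrom, bp, effect_allele, other_allele,
    odds_ratio, p_value) whose effect allele is the cohort minor allele.
    Null SNPs receive asymptotically uniform p-values, so a "p >= 0.99"
    non-significant subset always exists at scale.
    """
    from .association import scan  # local import: association consumes Cohort

    ref_cfg = replace(
        config,
        n_cases=n_ref_cases,
        n_controls=n_ref_controls,
        missing_rate=0.0,
        seed=seed,
    )
    ref = simulate_cohort(ref_cfg)
    stats = scan(ref)
    out = pd.DataFrame(
        {
            "rsid": stats["rsid"],
            "chrom": stats["chrom"],
            "bp": stats["bp"],
            "effect_allele": stats["minor_allele"],
            "other_allele": stats["major_allele"],
            "odds_ratio": stats["odds_ratio"],
            "p_value": stats["p_value"],
        }
    )
    out.attrs["source_label"] = source_label
    return out


# ---------------------------------------------------------------------------
# default study-scale configuration


def default_variant_specs(
    n_snps: int = 2000,
    n_causal: int = 20,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    abs_log_or_range: tuple[float, float] = (np.log(1.3), np.log(2.0)),
    block_size: int = 5,
    ambiguous_fraction: float = 0.0,
) -> tuple:
    """Variant panel with randomly placed causal SNPs.

    Causal effects get |log OR| uniform on ``abs_log_or_range`` with a
    random sign, i.e. ORs in roughly [0.5, 0.77] or [1.3, 2.0] — the
    magnitude range of replicated susceptibility loci for a common
    arrhythmia phenotype.  SNPs are laid on one synthetic chromosome in
    consecutive LD blocks of ``block_size``.
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, n_snps)
    log_or = np.zeros(n_snps)
    causal = rng.choice(n_snps, size=n_causal, replace=False)
    mag = rng.uniform(*abs_log_or_range, n_causal)
    sign = rng.choice([-1.0, 1.0], n_causal)
    log_or[causal] = sign * mag
    bp = np.cumsum(rng.integers(500, 5000, n_snps)) + 10_000
    specs = []
    for i in range(n_snps):
        if ambiguous_fraction > 0 and rng.random() < ambiguous_fraction:
            mi, ma = _AMBIGUOUS_PAIRS[rng.integers(len(_AMBIGUOUS_PAIRS))]
        else:
            mi, ma = _UNAMBIGUOUS_PAIRS[rng.integers(len(_UNAMBIGUOUS_PAIRS))]
        specs.append(
            VariantSpec(
                rsid=f"rs{100000 + i}",
                chrom="1",
                bp=int(bp[i]),
                maf=float(maf[i]),
                log_or=float(log_or[i]),
                block_id=i // block_size if block_size > 1 else None,
                minor_allele=mi,
                major_allele=ma,
            )
        )
    return tuple(specs)


def default_config(
    n_cases: int = 872,
    n_controls: int = 5486,
    n_snps: int = 2000,
    n_causal: int = 20,
    ld_block_r: float = 0.3,
    missing_rate: float = 0.01,
    seed: int = 0,
    **spec_kwargs,
) -> SimulationConfig:
    """Study-scale default: 872/5486 samples, 2,000 SNPs, 20 causal."""
    variants = default_variant_specs(
        n_snps=n_snps, n_causal=n_causal, seed=seed, **spec_kwargs
    )
    return SimulationConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        variants=variants,
        ld_block_r=ld_block_r,
        missing_rate=missing_rate,
        seed=seed,
    )
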