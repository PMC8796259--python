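"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from gwascnn import (
    Cohort,
    SimulationConfig,
    VariantSpec,
    default_config,
    harmonize,
    simulate_cohort,
    simulate_summary_stats,
)


def make_cohort_from_matrix(G, status=None, chrom=None, bp=None,
                            minor=None, major=None, rsid=None):
    """Hand-built cohort around an explicit genotype matrix."""
    G = np.asarray(G, dtype=float)
    n, p = G.shape
    status = np.asarray(
        status if status is not None else ([1] * (n // 2) + [0] * (n - n // 2))
    )
    rng = np.random.default_rng(0)
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "status": status,
            "registration_index": np.arange(1, n + 1),
            "age": np.round(rng.normal(55, 8, n), 2),
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
        }
    )
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(G, axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "rsid": rsid if rsid is not None else [f"rs{i}" for i in range(p)],
            "chrom": chrom if chrom is not None else ["1"] * p,
            "bp": bp if bp is not None else np.arange(1000, 1000 + 100 * p, 100),
            "minor_allele": minor if minor is not None else ["A"] * p,
            "major_allele": major if major is not None else ["G"] * p,
            "maf": maf,
        }
    )
    return Cohort(samples=samples, variants=variants, genotypes=G)


@pytest.fixture(scope="session")
def small_config():
    return default_config(
        n_cases=200, n_controls=800, n_snps=300, n_causal=5, seed=1
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_ref_stats(small_config):
    return simulate_summary_stats(small_config, 1500, 1500, seed=7)


@pytest.fixture(scope="session")
def small_harmonized(small_cohort, small_ref_stats):
    return harmonize(small_cohort, small_ref_stats)
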