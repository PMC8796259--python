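"""Reading and writing the pipeline's on-disk formats.

A cohort is serialized as a PLINK-dialect triplet plus sidecars:

* ``<prefix>.bim``   — variant table, PLINK column order
                       (chrom, rsid, 0, bp, allele1=minor, allele2=major)
* ``<prefix>.fam``   — sample table (FID, IID, 0, 0, sex 1=M/2=F,
                       phenotype 1=control/2=case)
* ``<prefix>.dosage.txt`` — plain-text additive genotype matrix, one
                       sample per row, whitespace-separated {0,1,2},
                       "NA" for missing
* ``<prefix>.covar.tsv``  — sample_id, registration_index, age
* ``<prefix>.truth.json`` — optional ground-truth sidecar (true log ORs,
                       block ids, seed) written for simulated cohorts

Summary statistics travel as TSV with header columns rsid, chrom, bp,
effect_allele, other_allele, and either odds_ratio or beta (log OR),
plus p_value.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import Cohort, SimulationConfig

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_summary_stats",
    "read_summary_stats",
    "write_metrics_json",
]

_SEX_CODE = {"M": 1, "F": 2}
_SEX_DECODE = {1: "M", 2: "F", 0: "U"}


def write_cohort(
    cohort: Cohort, prefix, config: Optional[SimulationConfig] = None
) -> dict:
    """Write the triplet (+sidecars) under ``prefix``; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "bim": prefix.with_suffix(".bim"),
        "fam": prefix.with_suffix(".fam"),
        "dosage": prefix.with_suffix(".dosage.txt"),
        "covar": prefix.with_suffix(".covar.tsv"),
    }

    v = cohort.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "rsid": v["rsid"],
            "cm": 0,
            "bp": v["bp"],
            "a1": v["minor_allele"],
            "a2": v["major_allele"],
        }
    )
    bim.to_csv(paths["bim"], sep="\t", header=False, index=False)

    s = cohort.samples
    fam = pd.DataFrame(
        {
            "fid": s["sample_id"],
            "iid": s["sample_id"],
            "pid": 0,
            "mid": 0,
            "sex": s["sex"].map(_SEX_CODE).fillna(0).astype(int),
            "pheno": s["status"].astype(int) + 1,
        }
    )
    fam.to_csv(paths["fam"], sep="\t", header=False, index=False)

    with open(paths["dosage"], "w") as fh:
        for row in cohort.genotypes:
            fh.write(
                " ".join("NA" if np.isnan(x) else str(int(x)) for x in row) + "\n"
            )

    s[["sample_id", "registration_index", "age"]].to_csv(
        paths["covar"], sep="\t", index=False
    )

    if config is not None:
        paths["truth"] = prefix.with_suffix(".truth.json")
        truth = {
            "seed": config.seed,
            "ld_block_r": config.ld_block_r,
            "variants": [
                {"rsid": sp.rsid, "log_or": sp.log_or, "block_id": sp.block_id}
                for sp in config.variants
            ],
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return {k: str(p) for k, p in paths.items()}


def read_cohort(prefix) -> Cohort:
    """Read a cohort triplet written by :func:`write_cohort`.

    Rejects genotype codes outside {0,1,2,NA}, dimension mismatches and
    duplicate rsids, naming the offending file and line.
    """
    prefix = Path(prefix)
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    dosage_path = prefix.with_suffix(".dosage.txt")
    covar_path = prefix.with_suffix(".covar.tsv")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "rsid", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "rsid": str, "a1": str, "a2": str},
    )
    if bim["rsid"].duplicated().any():
        dup = bim["rsid"][bim["rsid"].duplicated()].iloc[0]
        raise ValueError(f"{bim_path}: duplicate rsid {dup}")

    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype={"iid": str},
    )
    if not fam["pheno"].isin([1, 2]).all():
        raise ValueError(f"{fam_path}: phenotype codes must be 1 (control) or 2 (case)")

    n_var = len(bim)
    rows = []
    with open(dosage_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != n_var:
                raise ValueError(
                    f"{dosage_path}:{lineno}: expected {n_var} genotypes, "
                    f"got {len(fields)}"
                )
            row = np.empty(n_var)
            for j, tok in enumerate(fields):
                if tok == "NA":
                    row[j] = np.nan
                elif tok in ("0", "1", "2"):
                    row[j] = float(tok)
                else:
                    raise ValueError(
                        f"{dosage_path}:{lineno}: malformed genotype code "
                        f"{tok!r} (must be 0, 1, 2 or NA)"
                    )
            rows.append(row)
    genotypes = np.asarray(rows) if rows else np.empty((0, n_var))
    if genotypes.shape[0] != len(fam):
        raise ValueError(
            f"{dosage_path}: {genotypes.shape[0]} genotype rows but "
            f"{fam_path} lists {len(fam)} samples"
        )

    covar = pd.read_csv(covar_path, sep="\t", dtype={"sample_id": str})
    if list(covar["sample_id"]) != list(fam["iid"]):
        raise ValueError(f"{covar_path}: sample order disagrees with {fam_path}")

    samples = pd.DataFrame(
        {
            "sample_id": fam["iid"],
            "status": fam["pheno"].astype(int) - 1,
            "registration_index": covar["registration_index"].astype(int),
            "age": covar["age"].astype(float),
            "sex": fam["sex"].map(_SEX_DECODE),
        }
    )
    variants = pd.DataFrame(
        {
            "rsid": bim["rsid"],
            "chrom": bim["chrom"],
            "bp": bim["bp"].astype(int),
            "minor_allele": bim["a1"].str.upper(),
            "major_allele": bim["a2"].str.upper(),
        }
    )
    with np.errstate(invalid="ignore"):
        variants["maf"] = (
            np.nanmean(genotypes, axis=0) / 2.0 if len(genotypes) else np.nan
        )
    return Cohort(samples=samples, variants=variants, genotypes=genotypes)


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    cols = ["rsid", "chrom", "bp", "effect_allele", "other_allele",
            "odds_ratio", "p_value"]
    stats[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary_stats(path) -> pd.DataFrame:
    """Typed summary-statistics table.

    Accepts either an ``odds_ratio`` column or a ``beta`` (log OR)
    column, converting the latter.  Rows with non-positive OR or
    p-values outside (0, 1] are dropped; the number dropped is stored in
    ``.attrs["n_rejected"]``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    required = ["rsid", "chrom", "bp", "effect_allele", "other_allele", "p_value"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "odds_ratio" not in df.columns:
        if "beta" not in df.columns:
            raise ValueError(f"{path}: need an 'odds_ratio' or 'beta' column")
        df["odds_ratio"] = np.exp(df["beta"].astype(float))
    if df["rsid"].duplicated().any():
        dup = df["rsid"][df["rsid"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate rsid {dup}")
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    ok = (
        (df["odds_ratio"] > 0)
        & (df["p_value"] > 0)
        & (df["p_value"] <= 1)
        & np.isfinite(df["odds_ratio"])
    )
    out = df[ok].reset_index(drop=True)
    out.attrs["n_rejected"] = int((~ok).sum())
    out.attrs["source_label"] = str(path)
    return out


def write_metrics_json(report: dict, path) -> None:
    """Canonical (sorted-key, fixed-format) metrics JSON for replayability."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
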