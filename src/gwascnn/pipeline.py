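"""End-to-end orchestration with seeded reproducibility.

The full experiment mirrors the study design: simulate (or load) a
case-control genotype cohort, harmonize external summary statistics,
select SNP sets across the p-value threshold grid, train and evaluate
the CNN five times per threshold, then run the two negative controls
(p >= 0.99 SNP subset; registration-parity pseudo-labels), Grad-CAM
saliency for the best-validation-AUC model, and the LD-clumped PRS
baseline.  Every stochastic stage draws its seed from a master seed via
a declared counter scheme (SeedSequence([master, stage_counter])), and
a run manifest records config, seeds, input fingerprints and outputs so
a replay reproduces every metric file byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import association, evaluation, io as gio, prs as prs_mod, saliency as sal_mod
from .encoding import encode
from .features import CONTROL_RULE, STANDARD_THRESHOLDS, harmonize, select_features
from .model import ModelConfig, fit_baselines
from .simulate import SimulationConfig, default_config, simulate_cohort, \
    simulate_summary_stats

__all__ = ["stage_seed", "cmd_simulate", "run_experiment", "run_from_files",
            "replay"]


def stage_seed(master_seed: int, counter: int) -> int:
    """Deterministic per-stage seed: SeedSequence([master, counter])."""
    return int(np.random.SeedSequence([master_seed, counter]).generate_state(1)[0]
               % (2**31))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def cmd_simulate(
    out_prefix,
    config: Optional[SimulationConfig] = None,
    config_path=None,
    ref_cases: int = 3000,
    ref_controls: int = 3000,
    seed: int = 0,
) -> dict:
    """Simulate a cohort (+ reference summary stats) and write it to disk."""
    if config is None:
        if config_path is not None:
            config = SimulationConfig.from_json(config_path)
        else:
            config = default_config(seed=stage_seed(seed, 0))
    config.validate()
    cohort = simulate_cohort(config)
    paths = gio.write_cohort(cohort, out_prefix, config=config)
    stats = simulate_summary_stats(
        config, ref_cases, ref_controls, seed=stage_seed(seed, 1)
    )
    stats_path = Path(out_prefix).with_suffix(".sumstats.tsv")
    gio.write_summary_stats(stats, stats_path)
    paths["sumstats"] = str(stats_path)
    return paths


def run_experiment(
    cohort,
    stats,
    thresholds: Sequence[Union[float, str]] = STANDARD_THRESHOLDS,
    model_config: Optional[ModelConfig] = None,
    n_repeats: int = 5,
    seed: int = 0,
    saliency_threshold: float = 1.0e-5,
    prs_threshold: float = 1.0e-3,
    run_controls: bool = True,
    run_baselines: bool = False,
) -> dict:
    """Execute the full analysis in memory; returns a results dict.

    Per threshold: feature selection, encoding, five repeated stratified
    CNN train/test cycles.  The saliency panel uses the best-validation-
    AUC repeat at ``saliency_threshold`` and attributes the case score
    over the true cases only.  Controls reuse the feature sets (parity
    control at ``saliency_threshold``; the null control at p >= 0.99).
    """
    model_config = model_config or ModelConfig()
    harmonized = harmonize(cohort, stats)
    y = cohort.status
    results: dict = {"thresholds": {}, "seed": seed}

    counter = 10
    best_for_saliency = None
    X_sal = None
    feats_sal = None
    for t in thresholds:
        try:
            feats = select_features(harmonized, t)
        except ValueError as exc:
            results["thresholds"][str(t)] = {"error": str(exc)}
            continue
        Xt = encode(cohort, feats).X
        report, fitted = evaluation.run_repeats(
            Xt, y, config=model_config, n_repeats=n_repeats,
            seed=stage_seed(seed, counter), label=f"threshold_{t}",
            return_models=True,
        )
        entry = {"n_snps": len(feats), "report": report.to_dict()}
        if run_baselines:
            best_i = int(np.argmax([r["val_auc"] for r in report.rows]))
            model, plan = fitted[best_i]
            base = fit_baselines(Xt, y, plan, config=model_config,
                                 cnn_model=model)
            entry["baselines"] = {
                name: evaluation.auc_mann_whitney(p, y[plan.test])
                for name, p in base.items()
                if name in ("bayesian_cnn", "lasso", "ridge", "logistic")
            }
        results["thresholds"][str(t)] = entry
        if t == saliency_threshold:
            best_i = int(np.argmax([r["val_auc"] for r in report.rows]))
            best_for_saliency = fitted[best_i][0]
            X_sal, feats_sal = Xt, feats
        counter += 1

    if best_for_saliency is not None:
        cases = np.flatnonzero(y == 1)
        smap = sal_mod.grad_cam(
            best_for_saliency, X_sal[cases], col_ids=feats_sal.rsids
        )
        scan_all = association.scan(cohort)
        scan_sel = (
            scan_all.iloc[feats_sal.variant_indices].reset_index(drop=True)
        )
        comparison = sal_mod.saliency_vs_association(smap, scan_sel)
        results["saliency"] = {
            "threshold": saliency_threshold,
            "table": smap.to_frame().to_dict(orient="list"),
            "vs_association": comparison,
        }

    try:
        prs_model = prs_mod.clump(harmonized, cohort, threshold=prs_threshold)
        scores = prs_mod.score(prs_model, cohort)
        results["prs"] = {
            "threshold": prs_threshold,
            "n_retained": len(prs_model.retained),
            "auc": evaluation.auc_mann_whitney(
                scores["score"], scores["status"]
            ),
        }
    except (ValueError, KeyError) as exc:
        results["prs"] = {"error": str(exc)}

    if run_controls:
        if X_sal is not None:
            parity = evaluation.run_control_parity(
                X_sal, cohort, config=model_config, n_repeats=n_repeats,
                seed=stage_seed(seed, 101),
            )
            results["control_parity"] = parity.to_dict()
        try:
            null_rep = evaluation.run_control_null_snps(
                cohort, harmonized, config=model_config,
                n_repeats=n_repeats, seed=stage_seed(seed, 102),
            )
            results["control_null_snps"] = null_rep.to_dict()
        except ValueError as exc:
            results["control_null_snps"] = {"error": str(exc)}
    return results


def run_from_files(
    cohort_prefix,
    stats_path,
    out_dir,
    thresholds: Sequence[Union[float, str]] = STANDARD_THRESHOLDS,
    model_config: Optional[ModelConfig] = None,
    n_repeats: int = 5,
    seed: int = 0,
    **kwargs,
) -> dict:
    """File-level entry point: read inputs, run, write outputs + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = gio.read_cohort(cohort_prefix)
    stats = gio.read_summary_stats(stats_path)
    model_config = model_config or ModelConfig()
    results = run_experiment(
        cohort, stats, thresholds=thresholds, model_config=model_config,
        n_repeats=n_repeats, seed=seed, **kwargs,
    )

    outputs = {}
    for key in ("thresholds", "control_parity", "control_null_snps",
                "saliency", "prs"):
        if key in results:
            path = out_dir / f"{key}.json"
            gio.write_metrics_json(results[key], path)
            outputs[key] = str(path)

    cohort_prefix = Path(cohort_prefix)
    fingerprints = {}
    for suffix in (".bim", ".fam", ".dosage.txt", ".covar.tsv"):
        p = cohort_prefix.with_suffix(suffix)
        if p.exists():
            fingerprints[str(p)] = _sha256(p)
    fingerprints[str(stats_path)] = _sha256(stats_path)

    manifest = {
        "cohort_prefix": str(cohort_prefix),
        "stats_path": str(stats_path),
        "out_dir": str(out_dir),
        "thresholds": [str(t) for t in thresholds],
        "model_config": asdict(model_config),
        "n_repeats": n_repeats,
        "master_seed": seed,
        "seed_scheme": "SeedSequence([master_seed, stage_counter]) % 2^31",
        "kwargs": {k: str(v) for k, v in kwargs.items()},
        "input_fingerprints": fingerprints,
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results


def replay(manifest_path, out_dir=None) -> dict:
    """Re-run a recorded experiment; deterministic outputs are rewritten
    byte-identically when inputs are unchanged."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    for path, digest in manifest["input_fingerprints"].items():
        if _sha256(path) != digest:
            raise ValueError(f"input {path} changed since the recorded run")
    thresholds = [
        t if t == CONTROL_RULE else float(t) for t in manifest["thresholds"]
    ]
    kwargs = {}
    for k, v in manifest.get("kwargs", {}).items():
        if k in ("saliency_threshold", "prs_threshold"):
            kwargs[k] = float(v)
        elif k in ("run_controls", "run_baselines"):
            kwargs[k] = v == "True"
    return run_from_files(
        manifest["cohort_prefix"],
        manifest["stats_path"],
        out_dir or manifest["out_dir"],
        thresholds=thresholds,
        model_config=ModelConfig(**manifest["model_config"]),
        n_repeats=manifest["n_repeats"],
        seed=manifest["master_seed"],
        **kwargs,
    )
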