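"""Performance metrics, negative controls, matching and aggregation.

Metric panel per evaluated split: AUC (Mann-Whitney rank formulation
with tie correction), sensitivity, specificity, PPV, NPV, Gini
(= 2*AUC - 1), log-loss (probabilities clipped at 1e-7) and MSE.  The
operating point for the confusion-matrix metrics is the Youden-J
optimum found on the validation partition and frozen for test.

Negative controls mirror the study's validations: (a) the full pipeline
restricted to the non-significant p >= 0.99 SNP subset must lose its
discrimination, and (b) replacing the phenotype with the parity of the
sample registration index — a label with no heritable component — must
drive the AUC to chance regardless of the feature set.

Propensity-score matching (logistic propensity on age and sex, greedy
1:1 nearest-neighbor on the logit without replacement, caliper 0.2 SD)
provides the class-imbalance robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit as _logit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .model import ModelConfig, SplitPlan, make_splits, predict, train
from .simulate import Cohort

__all__ = [
    "auc_mann_whitney",
    "youden_threshold",
    "compute_metrics",
    "aggregate",
    "run_repeats",
    "run_control_null_snps",
    "run_control_parity",
    "parity_labels",
    "propensity_match",
]

_CLIP = 1e-7

METRIC_NAMES = ("auc", "sensitivity", "specificity", "ppv", "npv",
                "gini", "log_loss", "mse")


def auc_mann_whitney(probabilities, labels) -> float:
    """AUC via the rank-sum identity; ties contribute 1/2."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(p)  # average ranks handle ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def youden_threshold(probabilities, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1.

    Candidate cuts are midpoints between consecutive distinct scores;
    ties in J are broken toward the lower threshold (higher sensitivity).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    uniq = np.unique(p)
    if uniq.size == 1:
        return float(uniq[0])
    cuts = np.concatenate([[uniq[0] - 1e-12], (uniq[:-1] + uniq[1:]) / 2.0])
    best_j, best_t = -np.inf, cuts[0]
    n1 = y.sum()
    n0 = y.size - n1
    for t in cuts:
        pred = p > t
        sens = (pred & (y == 1)).sum() / n1
        spec = (~pred & (y == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def compute_metrics(probabilities, labels, threshold: float) -> dict:
    """One row of the metric panel at a fixed decision threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("metrics require both classes")
    auc = auc_mann_whitney(p, y)
    pred = p > threshold
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    pc = np.clip(p, _CLIP, 1.0 - _CLIP)
    return {
        "auc": auc,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if (tp + fp) else np.nan,
        "npv": tn / (tn + fn) if (tn + fn) else np.nan,
        "gini": 2.0 * auc - 1.0,
        "log_loss": float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc))),
        "mse": float(np.mean((p - y) ** 2)),
        "threshold": float(threshold),
    }


@dataclass
class MetricsReport:
    """Per-repeat metric rows plus their mean +/- SD."""

    rows: list  # one dict per repeat
    label: str = "main"
    n_repeats: int = 0

    def __post_init__(self) -> None:
        self.n_repeats = len(self.rows)

    @property
    def mean(self) -> dict:
        return {
            m: float(np.mean([r[m] for r in self.rows])) for m in METRIC_NAMES
        }

    @property
    def sd(self) -> dict:
        return {
            m: float(np.std([r[m] for r in self.rows], ddof=1))
            if len(self.rows) > 1
            else 0.0
            for m in METRIC_NAMES
        }

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_repeats": self.n_repeats,
            "rows": self.rows,
            "mean": self.mean,
            "sd": self.sd,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(r, repeat=i + 1) for i, r in enumerate(self.rows)]
        summary = dict(self.mean, repeat="mean")
        return pd.DataFrame(rows + [summary])


def aggregate(rows: list, label: str = "main") -> MetricsReport:
    """Mean +/- SD across repeated runs; per-repeat rows retained."""
    if len(rows) < 2:
        raise ValueError("aggregation needs at least 2 repeats")
    return MetricsReport(rows=list(rows), label=label)


def run_repeats(
    X,
    labels,
    config: Optional[ModelConfig] = None,
    n_repeats: int = 5,
    seed: int = 0,
    label: str = "main",
    return_models: bool = False,
):
    """Train/evaluate the CNN over repeated stratified shuffles.

    For every repeat a fresh split plan and a repeat-specific model seed
    are used; the Youden threshold is set on the validation partition
    and frozen for the test metrics.  Returns a :class:`MetricsReport`
    (and the per-repeat models with their plans when requested, for
    downstream best-model selection).
    """
    config = config or ModelConfig()
    y = np.asarray(labels, dtype=int)
    plans = make_splits(y, n_repeats=n_repeats, seed=seed)
    rows = []
    fitted = []
    for plan in plans:
        cfg = dc_replace(config, seed=seed * 1000 + plan.repeat_id)
        model = train(X, y, plan, cfg)
        p_val = predict(model, np.asarray(X)[plan.validation])
        thr = youden_threshold(p_val, y[plan.validation])
        p_te = predict(model, np.asarray(X)[plan.test])
        row = compute_metrics(p_te, y[plan.test], thr)
        row["val_auc"] = auc_mann_whitney(p_val, y[plan.validation])
        rows.append(row)
        if return_models:
            fitted.append((model, plan))
    report = MetricsReport(rows=rows, label=label)
    if return_models:
        return report, fitted
    return report


def parity_labels(cohort: Cohort) -> np.ndarray:
    """Registration-index parity pseudo-phenotype (odd=1, even=0)."""
    return (cohort.samples["registration_index"].to_numpy() % 2).astype(int)


def run_control_parity(
    X, cohort: Cohort, config=None, n_repeats: int = 5, seed: int = 0
) -> MetricsReport:
    """Pseudo-label control: genotypes untouched, labels replaced by the
    parity of the registration index.  Expected mean test AUC ~ 0.5."""
    y = parity_labels(cohort)
    return run_repeats(
        X, y, config=config, n_repeats=n_repeats, seed=seed, label="control_parity"
    )


def run_control_null_snps(
    cohort: Cohort, harmonized: pd.DataFrame, config=None,
    n_repeats: int = 5, seed: int = 0
) -> MetricsReport:
    """Non-significant-SNP control: the full cycle on the p >= 0.99 set."""
    from .encoding import encode
    from .features import CONTROL_RULE, select_features

    control = select_features(harmonized, CONTROL_RULE)
    Xc = encode(cohort, control).X
    return run_repeats(
        Xc,
        cohort.status,
        config=config,
        n_repeats=n_repeats,
        seed=seed,
        label="control_null_snps",
    )


def propensity_match(
    cohort: Cohort, seed: int = 0, caliper_sd: float = 0.2
) -> tuple[Cohort, pd.DataFrame]:
    """1:1 greedy nearest-neighbor matching on the propensity logit.

    The propensity is a logistic regression of status on age and sex;
    cases are visited in random order (seeded) and matched without
    replacement to the nearest control within a caliper of
    ``caliper_sd`` pooled SD of the logit.  Returns the matched
    sub-cohort and the pair table; warns if more than 20% of cases find
    no control inside the caliper.
    """
    s = cohort.samples
    covars = np.column_stack(
        [s["age"].to_numpy(dtype=float), (s["sex"] == "M").to_numpy(dtype=float)]
    )
    y = cohort.status
    ps = (
        LogisticRegression(max_iter=1000)
        .fit(covars, y)
        .predict_proba(covars)[:, 1]
    )
    lg = _logit(np.clip(ps, 1e-12, 1 - 1e-12))
    caliper = caliper_sd * lg.std(ddof=1)

    rng = np.random.default_rng(seed)
    case_idx = rng.permutation(np.flatnonzero(y == 1))
    ctrl_idx = np.flatnonzero(y == 0)
    available = np.ones(ctrl_idx.size, dtype=bool)
    pairs = []
    unmatched = 0
    for ci in case_idx:
        open_ = np.flatnonzero(available)
        if open_.size == 0:
            unmatched += 1
            continue
        d = np.abs(lg[ctrl_idx[open_]] - lg[ci])
        j = int(np.argmin(d))
        if d[j] <= caliper:
            pairs.append((ci, int(ctrl_idx[open_[j]]), float(d[j])))
            available[open_[j]] = False
        else:
            unmatched += 1
    if unmatched > 0.2 * case_idx.size:
        import warnings

        warnings.warn(
            f"{unmatched} of {case_idx.size} cases had no control within "
            f"the caliper ({caliper:.4g} on the logit scale)",
            stacklevel=2,
        )
    pair_table = pd.DataFrame(pairs, columns=["case_index", "control_index",
                                              "logit_distance"])
    keep = np.sort(
        np.concatenate(
            [pair_table["case_index"].to_numpy(),
             pair_table["control_index"].to_numpy()]
        )
    ).astype(int)
    matched = Cohort(
        samples=s.iloc[keep].reset_index(drop=True),
        variants=cohort.variants.copy(),
        genotypes=cohort.genotypes[keep],
    )
    return matched, pair_table
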