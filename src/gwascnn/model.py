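"""The CNN genotype classifier, its training protocol, and baselines.

Architecture (two hidden layers): input N x 1 (N = feature-set size,
SNPs in genomic order, raw codes {-1,0,1,2}) -> 1D convolution
(n_filters, kernel_size, stride, ReLU) -> flatten -> dropout -> fully
connected (fc_units, ReLU) -> single logistic output unit.  Training
minimizes binary cross-entropy with Adam, stops early on the validation
loss, and restores the best-epoch weights.  Repeated stratified
64/16/20 train/validation/test splits provide the evaluation protocol.

The network, its backpropagation, Adam and Monte-Carlo dropout are
implemented directly on NumPy arrays: the model is small (one conv +
one dense hidden layer) and exact control over gradients is required
for the Grad-CAM attribution (:mod:`gwascnn.saliency`), which consumes
the convolutional activations and the analytic gradient of the
pre-sigmoid case score with respect to them.

Comparison baselines: the same CNN under Monte-Carlo dropout at rate
0.5 (a Bayesian approximation), and L1-penalized, L2-penalized and
unpenalized logistic regression via scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ModelConfig",
    "SplitPlan",
    "TrainedModel",
    "make_splits",
    "train",
    "predict",
    "conv_activations_and_score_grad",
    "fit_baselines",
]

_EPS = 1e-7  # probability clipping in the loss


@dataclass(frozen=True)
class ModelConfig:
    n_filters: int = 16
    kernel_size: int = 2
    stride: int = 1
    fc_units: int = 32
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 10
    class_weight: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if not (0 <= self.patience < self.max_epochs):
            raise ValueError("patience must be < max_epochs")


@dataclass
class SplitPlan:
    """One repeat's disjoint, exhaustive 64/16/20 stratified partition."""

    repeat_id: int
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    stratified: bool = True
    seed: int = 0


@dataclass
class TrainedModel:
    config: ModelConfig
    params: dict  # Wc (K,k), bc (K,), W1 (L*K, H), b1 (H,), w2 (H,), b2 ()
    training_history: list  # per-epoch {"train_loss", "val_loss"}
    best_epoch: int  # 1-based
    n_snps: int

    @property
    def conv_out_len(self) -> int:
        k, s = self.config.kernel_size, self.config.stride
        return (self.n_snps - k) // s + 1


def make_splits(labels, n_repeats: int = 5, seed: int = 0) -> list:
    """Repeated stratified shuffles into 64% train / 16% validation / 20% test.

    Each repeat reshuffles with a repeat-specific seed, holds out a
    stratified 20% test set, then splits the remainder 80/20 into train
    and validation, so the case fraction is equal across partitions
    within rounding.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < n_repeats:
        raise ValueError(
            f"smallest class has {counts.min()} members; need >= {n_repeats}"
        )
    plans = []
    for r in range(1, n_repeats + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        tr_all, va_all, te_all = [], [], []
        for c in classes:
            idx = rng.permutation(np.flatnonzero(y == c))
            n = idx.size
            n_te = int(round(0.20 * n))
            n_va = int(round(0.16 * n))
            te_all.append(idx[:n_te])
            va_all.append(idx[n_te : n_te + n_va])
            tr_all.append(idx[n_te + n_va :])
        plans.append(
            SplitPlan(
                repeat_id=r,
                train=np.sort(np.concatenate(tr_all)),
                validation=np.sort(np.concatenate(va_all)),
                test=np.sort(np.concatenate(te_all)),
                seed=seed,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# network internals


def _init_params(cfg: ModelConfig, n_snps: int, rng) -> dict:
    K, k = cfg.n_filters, cfg.kernel_size
    L = (n_snps - k) // cfg.stride + 1
    if L < 1:
        raise ValueError(f"kernel_size {k} exceeds input width {n_snps}")
    flat = L * K
    return {
        "Wc": rng.normal(0.0, np.sqrt(2.0 / k), (K, k)),
        "bc": np.zeros(K),
        "W1": rng.normal(0.0, np.sqrt(2.0 / flat), (flat, cfg.fc_units)),
        "b1": np.zeros(cfg.fc_units),
        "w2": rng.normal(0.0, np.sqrt(2.0 / cfg.fc_units), cfg.fc_units),
        "b2": np.zeros(()),
    }


def _conv_windows(X: np.ndarray, k: int, stride: int) -> np.ndarray:
    return sliding_window_view(X, k, axis=1)[:, ::stride, :]


def _forward(params, X, cfg: ModelConfig, drop_mask=None):
    """Returns (logit, cache).  ``drop_mask`` applies inverted dropout."""
    W = _conv_windows(X, cfg.kernel_size, cfg.stride)  # (B, L, k)
    Z = np.tensordot(W, params["Wc"], axes=([2], [1])) + params["bc"]  # (B, L, K)
    A = np.maximum(Z, 0.0)
    B = X.shape[0]
    D = A.reshape(B, -1)
    if drop_mask is not None:
        D = D * drop_mask
    Z1 = D @ params["W1"] + params["b1"]
    H = np.maximum(Z1, 0.0)
    logit = H @ params["w2"] + params["b2"]
    return logit, {"W": W, "Z": Z, "A": A, "D": D, "Z1": Z1, "H": H}


def _weighted_bce(logit, y, w):
    p = np.clip(expit(logit), _EPS, 1.0 - _EPS)
    return float(-np.average(y * np.log(p) + (1 - y) * np.log(1 - p), weights=w))


def _backward(params, cache, logit, y, w, cfg: ModelConfig, drop_mask):
    p = expit(logit)
    wn = w / w.sum()
    dlogit = (p - y) * wn  # d(weighted BCE)/dlogit
    g = {}
    g["w2"] = cache["H"].T @ dlogit
    g["b2"] = dlogit.sum()
    dH = np.outer(dlogit, params["w2"])
    dZ1 = dH * (cache["Z1"] > 0)
    g["W1"] = cache["D"].T @ dZ1
    g["b1"] = dZ1.sum(0)
    dD = dZ1 @ params["W1"].T
    if drop_mask is not None:
        dD = dD * drop_mask
    dA = dD.reshape(cache["A"].shape)
    dZ = dA * (cache["Z"] > 0)
    g["Wc"] = np.einsum("blk,bli->ki", dZ, cache["W"])
    g["bc"] = dZ.sum((0, 1))
    return g


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _class_weights(y_train, enabled: bool) -> dict:
    if not enabled:
        return {0: 1.0, 1: 1.0}
    n = y_train.size
    n1 = int(y_train.sum())
    n0 = n - n1
    return {0: n / (2.0 * n0), 1: n / (2.0 * n1)}


def train(X, labels, plan: SplitPlan, config: ModelConfig) -> TrainedModel:
    """Fit the CNN on the plan's train partition with early stopping.

    The validation loss (same class weighting as training) is evaluated
    after every epoch; training stops when it has not improved for
    ``patience`` epochs and the best-epoch weights are restored.
    """
    config.validate()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels, dtype=float)
    n_snps = X.shape[1]
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, n_snps, rng)
    opt = _Adam(params, config.learning_rate)

    Xtr, ytr = X[plan.train], y[plan.train]
    Xva, yva = X[plan.validation], y[plan.validation]
    cw = _class_weights(ytr, config.class_weight)
    wtr = np.where(ytr == 1, cw[1], cw[0])
    wva = np.where(yva == 1, cw[1], cw[0])

    flat = ((n_snps - config.kernel_size) // config.stride + 1) * config.n_filters
    keep = 1.0 - config.dropout_rate

    history = []
    best_val = np.inf
    best_epoch = 0
    best_params = None
    wait = 0
    n_tr = Xtr.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n_tr)
        ep_loss = 0.0
        ep_w = 0.0
        for start in range(0, n_tr, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb, wb = Xtr[sel], ytr[sel], wtr[sel]
            if config.dropout_rate > 0.0:
                mask = (rng.random((xb.shape[0], flat)) < keep) / keep
            else:
                mask = None
            logit, cache = _forward(params, xb, config, drop_mask=mask)
            loss = _weighted_bce(logit, yb, wb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch mean logit {np.mean(logit):.3g}); "
                    "lower the learning rate"
                )
            grads = _backward(params, cache, logit, yb, wb, config, mask)
            opt.step(params, grads)
            ep_loss += loss * wb.sum()
            ep_w += wb.sum()
        val_logit, _ = _forward(params, Xva, config)
        val_loss = _weighted_bce(val_logit, yva, wva)
        history.append(
            {"epoch": epoch, "train_loss": ep_loss / ep_w, "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in params.items()}
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    return TrainedModel(
        config=config,
        params=best_params,
        training_history=history,
        best_epoch=best_epoch,
        n_snps=n_snps,
    )


def predict(
    model: TrainedModel,
    X,
    mc_dropout: bool = False,
    n_passes: int = 100,
    mc_seed: int = 0,
):
    """Per-sample case probabilities in [0, 1].

    Deterministic by default (dropout disabled at inference).  With
    ``mc_dropout`` the model runs ``n_passes`` stochastic forward passes
    at the configured dropout rate and returns ``(mean, sd)`` per
    sample — the Monte-Carlo-dropout Bayesian approximation.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.n_snps:
        raise ValueError(
            f"input has {X.shape[1]} SNPs but model expects {model.n_snps}"
        )
    cfg = model.config
    if not mc_dropout:
        logit, _ = _forward(model.params, X, cfg)
        return expit(logit)
    rng = np.random.default_rng(mc_seed)
    keep = 1.0 - cfg.dropout_rate
    flat = model.conv_out_len * cfg.n_filters
    acc = np.zeros((n_passes, X.shape[0]))
    for i in range(n_passes):
        mask = (rng.random((X.shape[0], flat)) < keep) / keep
        logit, _ = _forward(model.params, X, cfg, drop_mask=mask)
        acc[i] = expit(logit)
    return acc.mean(0), acc.std(0)


def conv_activations_and_score_grad(model: TrainedModel, X):
    """Conv-layer activations A and d(logit)/dA for Grad-CAM.

    Returns ``(A, dA)`` of shape (samples, conv positions, filters).
    The gradient is taken at the pre-sigmoid case score and computed
    analytically through the dense head (dropout off).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.n_snps:
        raise ValueError(
            f"input has {X.shape[1]} SNPs but model expects {model.n_snps}"
        )
    p = model.params
    _, cache = _forward(p, X, model.config)
    dH = np.broadcast_to(p["w2"], cache["H"].shape)
    dZ1 = dH * (cache["Z1"] > 0)
    dD = dZ1 @ p["W1"].T
    dA = dD.reshape(cache["A"].shape)
    return cache["A"], dA


def fit_baselines(
    X,
    labels,
    plan: SplitPlan,
    config: Optional[ModelConfig] = None,
    cnn_model: Optional[TrainedModel] = None,
    mc_passes: int = 100,
) -> dict:
    """Test-set probabilities for the four comparison methods.

    ``bayesian_cnn`` — the trained CNN under MC dropout at rate 0.5;
    ``lasso`` / ``ridge`` — L1/L2-penalized logistic regression;
    ``logistic`` — unpenalized logistic regression (falls back to a
    near-zero ridge penalty, flagged in ``notes``, if the unpenalized
    fit is singular or fails to converge).  All methods share the same
    split.
    """
    config = config or ModelConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    Xtr, ytr = X[plan.train], y[plan.train]
    Xte = X[plan.test]
    cw = "balanced" if config.class_weight else None
    out: dict = {"notes": {}}

    if cnn_model is None:
        mc_cfg = replace(config, dropout_rate=0.5)
        cnn_model = train(X, y, plan, mc_cfg)
    mc_cfg = (
        cnn_model.config
        if cnn_model.config.dropout_rate > 0
        else replace(cnn_model.config, dropout_rate=0.5)
    )
    mc_model = TrainedModel(
        config=replace(mc_cfg, dropout_rate=0.5),
        params=cnn_model.params,
        training_history=cnn_model.training_history,
        best_epoch=cnn_model.best_epoch,
        n_snps=cnn_model.n_snps,
    )
    mean, sd = predict(mc_model, Xte, mc_dropout=True, n_passes=mc_passes,
                       mc_seed=config.seed)
    out["bayesian_cnn"] = mean
    out["bayesian_cnn_sd"] = sd

    lasso = LogisticRegression(
        penalty="l1", solver="liblinear", C=1.0, class_weight=cw, max_iter=2000
    ).fit(Xtr, ytr)
    out["lasso"] = lasso.predict_proba(Xte)[:, 1]

    ridge = LogisticRegression(
        penalty="l2", C=1.0, class_weight=cw, max_iter=2000
    ).fit(Xtr, ytr)
    out["ridge"] = ridge.predict_proba(Xte)[:, 1]

    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logreg = LogisticRegression(
                penalty=None, class_weight=cw, max_iter=2000
            ).fit(Xtr, ytr)
        coef = np.concatenate([logreg.coef_.ravel(), logreg.intercept_])
        if not np.isfinite(coef).all() or np.abs(coef).max() > 1e6:
            raise FloatingPointError("diverged coefficients")
        out["logistic"] = logreg.predict_proba(Xte)[:, 1]
    except Exception as exc:  # singular/separated fit with N >= M
        fallback = LogisticRegression(
            penalty="l2", C=1e6, class_weight=cw, max_iter=2000
        ).fit(Xtr, ytr)
        out["logistic"] = fallback.predict_proba(Xte)[:, 1]
        out["notes"]["logistic"] = f"fell back to near-zero ridge penalty ({exc})"
    return out
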