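"""Grad-CAM attribution of the CNN's case score to individual SNPs.

For each patient, the convolutional feature map A^k_u (filter k,
position u) and the gradient of the pre-sigmoid case score y with
respect to it give filter importances

    alpha_k = mean_u  dy / dA^k_u,

and the localized relevance L_u = ReLU(sum_k alpha_k A^k_u).  L (length
= conv output length) is upsampled to the SNP axis by linear
interpolation, producing one non-negative row of the 2D saliency map S
(patients x SNPs).  The per-SNP mean of S, divided by its maximum so
the top SNP scores exactly 1.0, is the headline saliency profile that
is compared against the association scan's Manhattan statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import TrainedModel, conv_activations_and_score_grad

__all__ = ["SaliencyMap", "grad_cam", "saliency_vs_association"]


@dataclass
class SaliencyMap:
    per_patient: np.ndarray  # (patients, SNPs), >= 0
    mean_per_snp: np.ndarray
    normalized_mean: np.ndarray
    col_ids: Optional[list] = None

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.mean_per_snp, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, order.size + 1)
        return pd.DataFrame(
            {
                "rsid": self.col_ids
                if self.col_ids is not None
                else [f"snp{i}" for i in range(self.mean_per_snp.size)],
                "mean_saliency": self.mean_per_snp,
                "normalized_saliency": self.normalized_mean,
                "rank": rank,
            }
        )


def grad_cam(
    model: TrainedModel, X_patients, col_ids: Optional[list] = None
) -> SaliencyMap:
    """Per-patient, per-SNP Grad-CAM scores for the case class.

    ``X_patients`` is typically the encoded genotypes of the true cases.
    Raises if the model has no convolutional layer output (kernel wider
    than the input) or the patient set is empty.
    """
    X = np.asarray(X_patients, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X_patients must be a non-empty 2D matrix")
    A, dA = conv_activations_and_score_grad(model, X)  # (B, L, K)
    if A.shape[1] < 1:
        raise ValueError("model has no convolutional output positions")
    alpha = dA.mean(axis=1)  # (B, K): gradient averaged over positions
    L = np.maximum(np.einsum("bk,blk->bl", alpha, A), 0.0)  # (B, L)

    n_snps = model.n_snps
    L_len = L.shape[1]
    if L_len == n_snps:
        S = L
    else:
        # conv position u covers SNPs [u*stride, u*stride + k - 1]; anchor
        # each relevance value at its receptive-field centre, then linearly
        # interpolate onto the SNP axis (constant extension at the edges)
        k, s = model.config.kernel_size, model.config.stride
        src = np.arange(L_len) * s + (k - 1) / 2.0
        dst = np.arange(n_snps, dtype=float)
        S = np.empty((X.shape[0], n_snps))
        for i in range(X.shape[0]):
            S[i] = np.interp(dst, src, L[i])

    mean = S.mean(axis=0)
    mmax = mean.max()
    norm = mean / mmax if mmax > 0 else np.zeros_like(mean)
    return SaliencyMap(
        per_patient=S, mean_per_snp=mean, normalized_mean=norm, col_ids=col_ids
    )


def saliency_vs_association(
    smap: SaliencyMap,
    assoc_stats: pd.DataFrame,
    neg_log10_cap: float = 50.0,
    top_fraction: float = 0.05,
    overlap_thresholds: tuple = (5.0e-8, 1.0e-5),
) -> dict:
    """Compare the saliency profile with the association scan.

    Both inputs must cover the same SNPs in the same order.  Reports the
    Pearson correlation between the normalized mean saliency and
    -log10 p (capped at ``neg_log10_cap`` to bound near-zero p-values),
    the top-``top_fraction`` saliency SNPs, and their overlap with the
    SNPs passing each association threshold.  A zero-variance input
    makes the correlation undefined; it is reported as None, not NaN.
    """
    if len(assoc_stats) != smap.normalized_mean.size:
        raise ValueError(
            f"saliency covers {smap.normalized_mean.size} SNPs but the "
            f"association table has {len(assoc_stats)}"
        )
    sal = smap.normalized_mean
    nlp = np.minimum(-np.log10(assoc_stats["p_value"].to_numpy()), neg_log10_cap)
    if np.std(sal) == 0.0 or np.std(nlp) == 0.0:
        corr = None
    else:
        corr = float(np.corrcoef(sal, nlp)[0, 1])

    n = sal.size
    n_top = max(1, int(np.ceil(top_fraction * n)))
    top_idx = np.argsort(-sal, kind="stable")[:n_top]
    rsids = assoc_stats["rsid"].to_numpy()
    overlaps = {}
    for t in overlap_thresholds:
        sig = set(np.flatnonzero(assoc_stats["p_value"].to_numpy() < t))
        overlaps[t] = {
            "n_significant": len(sig),
            "n_in_top": len(sig & set(top_idx.tolist())),
        }
    return {
        "pearson_r": corr,
        "top_fraction": top_fraction,
        "top_rsids": list(rsids[top_idx]),
        "overlap": overlaps,
    }
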