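"""Signed co-expression graph: power adjacency, soft-power pick, binarization.

The gene graph is the signed WGCNA adjacency: for genes i, j with Pearson
correlation r_ij over the training observations,

    C_ij = ((1 + r_ij) / 2) ** alpha

so perfectly anti-correlated genes get weight 0, uncorrelated genes get
0.5**alpha, and perfectly correlated genes weight 1.  The soft power alpha
is the smallest candidate whose scale-free topology fit reaches the target
R^2 (the classic pickSoftThreshold rule); the soft adjacency is then
binarized with a strict threshold into the edge matrix the attention layers
consume, keeping self-loops so every node attends to itself.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_POWERS = tuple(range(1, 21))
SCALE_FREE_R2_TARGET = 0.8
FALLBACK_POWER = 6.0


@dataclass
class CoexpressionGraph:
    gene_ids: list[str]
    C: np.ndarray  # soft adjacency in [0,1], diagonal 1
    alpha: float
    adj_thresh: float
    A: np.ndarray  # binary edges, diagonal 1 (self-loops)
    training_fingerprint: str = ""
    r2_trace: dict[float, float] = field(default_factory=dict)


def training_observations(features: np.ndarray) -> np.ndarray:
    """Genes x observations matrix from an integrated feature tensor.

    Each training pair contributes its expression channel and its
    methylation channel as two separate observations of every gene, so the
    correlation treats the channels symmetrically.
    """
    if features.ndim != 3:
        raise ValueError("expected features of shape (pairs, genes, channels)")
    n_pairs, n_genes, n_ch = features.shape
    return features.transpose(1, 0, 2).reshape(n_genes, n_pairs * n_ch)


def fingerprint(obs: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(obs).tobytes()).hexdigest()[:16]


def signed_adjacency(obs: np.ndarray, alpha: float) -> np.ndarray:
    """((1 + pearson) / 2) ** alpha over gene pairs; constant genes get r = 0."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if obs.shape[1] < 3:
        raise ValueError("need at least 3 observations per gene")
    const = obs.std(axis=1) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant genes: correlation set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(obs)
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.nan_to_num(r, copy=False)
    np.clip(r, -1.0, 1.0, out=r)
    C = ((1.0 + r) / 2.0) ** alpha
    np.fill_diagonal(C, 1.0)
    return C


def scale_free_fit(C: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index for a soft adjacency.

    Connectivities k_i = sum_{j != i} C_ij are binned; log10(frequency) is
    regressed on log10(mean connectivity) per occupied bin, and the index is
    -sign(slope) * R^2 so only degree distributions that *decay* with
    connectivity score high.
    """
    k = C.sum(axis=1) - np.diag(C)
    if np.allclose(k, k[0]):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if len(members) == 0 or members.mean() <= 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(len(members) / len(k)))
    if len(xs) < 3:
        return float("nan")
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_power(
    obs: np.ndarray,
    candidate_powers: tuple[float, ...] = DEFAULT_POWERS,
    r2_target: float = SCALE_FREE_R2_TARGET,
) -> tuple[float, dict[float, float]]:
    """Smallest candidate power reaching the scale-free fit target.

    Returns (alpha, R^2 trace).  If no candidate reaches the target the
    best-fitting one is returned with a warning; fully degenerate
    connectivity falls back to a conventional default power.
    """
    if not candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    trace: dict[float, float] = {}
    for p in candidate_powers:
        r2 = scale_free_fit(signed_adjacency(obs, p))
        trace[float(p)] = r2
        if np.isfinite(r2) and r2 >= r2_target:
            return float(p), trace
    finite = {p: r2 for p, r2 in trace.items() if np.isfinite(r2)}
    if not finite:
        warnings.warn(
            f"degenerate connectivity at every candidate power; "
            f"falling back to alpha={FALLBACK_POWER}"
        )
        return FALLBACK_POWER, trace
    best = max(finite, key=finite.get)
    warnings.warn(
        f"no candidate power reached scale-free R^2 >= {r2_target}; "
        f"using best fit alpha={best} (R^2={finite[best]:.3f})"
    )
    return best, trace


def binarize(C: np.ndarray, adj_thresh: float) -> np.ndarray:
    """Edge matrix: A_ij = 1 iff C_ij > adj_thresh (strict); diagonal forced 1."""
    if not 0 < adj_thresh < 1:
        raise ValueError("adj_thresh must be in (0,1)")
    A = (C > adj_thresh).astype(np.int8)
    np.fill_diagonal(A, 1)
    if A.sum() == len(A):
        warnings.warn("graph has no off-diagonal edges (self-loops only)")
    return A


def tune_adj_thresh(
    train_ds,
    validation_ds,
    candidate_thresholds: tuple[float, ...],
    alpha: float,
    model_config=None,
) -> tuple[float, dict[float, float]]:
    """Grid-search the binarization threshold on validation AUROC.

    Trains a budget-capped attention model per candidate and keeps the
    threshold with the best validation AUROC; ties break toward the sparser
    graph (larger threshold).  Per-candidate training failures are reported
    and skipped.
    """
    from sklearn.metrics import roc_auc_score

    from . import model as _model

    if not candidate_thresholds:
        raise ValueError("candidate_thresholds must be non-empty")
    for t in candidate_thresholds:
        if not 0 < t < 1:
            raise ValueError(f"adj_thresh candidate {t} not in (0,1)")
    if model_config is None:
        model_config = _model.MLAGNNConfig(epochs=15, patience=5)
    obs = training_observations(train_ds.features)
    C = signed_adjacency(obs, alpha)
    scores: dict[float, float] = {}
    for t in candidate_thresholds:
        g = CoexpressionGraph(
            gene_ids=list(train_ds.gene_ids), C=C, alpha=alpha,
            adj_thresh=t, A=binarize(C, t), training_fingerprint=fingerprint(obs),
        )
        try:
            params, _ = _model.train(train_ds, g, model_config)
            prob = _model.predict_proba(validation_ds.features, g, params, model_config)
            scores[t] = float(roc_auc_score(validation_ds.y, prob))
        except Exception as exc:  # isolate per-candidate failures
            logger.warning("candidate adj_thresh=%s failed: %s", t, exc)
    if not scores:
        raise RuntimeError("every candidate threshold failed to train")
    best = max(sorted(scores), key=lambda t: (scores[t], t))
    return best, scores


def build_graph(
    train_features: np.ndarray,
    gene_ids: list[str],
    alpha: float | None = None,
    adj_thresh: float = 0.5,
) -> CoexpressionGraph:
    """Soft adjacency + binarization from the training feature tensor only."""
    obs = training_observations(train_features)
    if alpha is None:
        alpha, trace = pick_soft_power(obs)
    else:
        trace = {}
    C = signed_adjacency(obs, alpha)
    A = binarize(C, adj_thresh)
    logger.info(
        "graph: alpha=%s adj_thresh=%s edges=%d", alpha, adj_thresh,
        int(A.sum() - len(A)) // 2,
    )
    return CoexpressionGraph(
        gene_ids=list(gene_ids), C=C, alpha=float(alpha), adj_thresh=adj_thresh,
        A=A, training_fingerprint=fingerprint(obs), r2_trace=trace,
    )
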