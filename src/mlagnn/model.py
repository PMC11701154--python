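"""Multi-level attention graph neural network and full-gradient saliency.

Each combined sample is a graph: one node per panel gene carrying a
two-channel feature (expression, methylation), with edges from the binary
co-expression matrix.  Two stacked graph-attention (GAT) layers produce the
level features

    G1  — the input node features (untouched by attention),
    G2  — node features after the first attention layer,
    G3  — node features after the second,

G2 and G3 are linearly projected to a common width (G2', G3'), each level is
flattened node-major into a graph-level vector (F1, F2, F3), and the fused
representation F = [F1 | F2 | F3] feeds a linear tumor/normal head.

Gene importance is scored by full-gradient saliency (FGS): at each level the
per-node attribution is gradient x feature summed over that node's
coordinates, plus the bias-path term of the layer producing the level
(bias x gradient, likewise per node); per-gene scores are the mean absolute
attribution over the scored samples, reported per level and for the fusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import (
    Tensor,
    add_const,
    concat,
    cross_entropy_with_logits,
    mul_const,
)
from .graph import CoexpressionGraph
from .integrate import IntegratedDataset

logger = logging.getLogger(__name__)

MASK_NEG = -1e9


@dataclass(frozen=True)
class MLAGNNConfig:
    """Model and training hyperparameters (learning rate and dropout follow
    the reference configuration: lr = 0.005, dropout = 0.4)."""

    in_channels: int = 2
    gat_hidden_dim: int = 8
    attention_heads: int = 1
    leaky_slope: float = 0.2
    projection_dim: int = 8
    dropout: float = 0.4
    learning_rate: float = 0.005
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    class_weighting: str = "inverse_frequency"  # or "none"
    patience: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0,1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.class_weighting not in ("none", "inverse_frequency"):
            raise ValueError("class_weighting must be 'none' or 'inverse_frequency'")


@dataclass
class LevelFeatures:
    """All intermediate representations of one forward pass (Tensor-valued)."""

    G1: Tensor
    G2: Tensor
    G3: Tensor
    G2p: Tensor
    G3p: Tensor
    F1: Tensor
    F2: Tensor
    F3: Tensor
    F: Tensor
    attention: list[np.ndarray] = field(default_factory=list)


@dataclass
class SaliencyReport:
    """Per-gene FGS scores at levels F1/F2/F3 and fused F, with rankings."""

    scores: pd.DataFrame  # index gene_id; columns score_F1..score_F, rank_F
    top: dict[str, list[str]]  # level -> top-k gene ids
    aggregation: str = "mean_abs_over_samples"


# -- parameters ---------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan = sum(shape[-2:]) if len(shape) > 1 else shape[0] + 1
    limit = np.sqrt(6.0 / fan)
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: MLAGNNConfig, n_genes: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    h, k = config.gat_hidden_dim, config.attention_heads
    p = config.projection_dim
    params: dict[str, np.ndarray] = {}
    dims_in = [config.in_channels, h * k]
    for layer in (1, 2):
        d_in = dims_in[layer - 1]
        for head in range(k):
            tag = f"gat{layer}_h{head}"
            params[f"{tag}_W"] = _glorot(rng, (d_in, h))
            params[f"{tag}_asrc"] = _glorot(rng, (h, 1))
            params[f"{tag}_adst"] = _glorot(rng, (h, 1))
        params[f"gat{layer}_b"] = np.zeros(h * k)
    params["proj2_W"] = _glorot(rng, (h * k, p))
    params["proj2_b"] = np.zeros(p)
    params["proj3_W"] = _glorot(rng, (h * k, p))
    params["proj3_b"] = np.zeros(p)
    f_dim = n_genes * (config.in_channels + 2 * p)
    params["head_W"] = _glorot(rng, (f_dim, 2))
    params["head_b"] = np.zeros(2)
    return params


def _as_tensors(params: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=True) for k, v in params.items()}


# -- forward ------------------------------------------------------------------


def gat_layer(
    x: Tensor,
    mask_add: np.ndarray,
    pt: dict[str, Tensor],
    layer: int,
    config: MLAGNNConfig,
    attention_out: list[np.ndarray] | None = None,
) -> Tensor:
    """One multi-head graph-attention update.

    Per edge (i, j) with A_ij = 1: e_ij = LeakyReLU(a^T [W h_i || W h_j]);
    attention is the softmax of e_ij over the neighborhood of i (additive
    mask excludes non-edges); the node update is the attention-weighted sum
    of transformed neighbors plus a bias, heads concatenated, ELU applied.
    """
    heads = []
    for head in range(config.attention_heads):
        tag = f"gat{layer}_h{head}"
        H = x.matmul(pt[f"{tag}_W"])  # (B, N, h)
        s_src = H.matmul(pt[f"{tag}_asrc"])  # (B, N, 1)
        s_dst = H.matmul(pt[f"{tag}_adst"])  # (B, N, 1)
        e = s_src + s_dst.transpose_last()  # e_ij = a_src.Wh_i + a_dst.Wh_j
        e = add_const(e.leaky_relu(config.leaky_slope), mask_add)
        att = e.softmax_last()
        if attention_out is not None:
            attention_out.append(att.data)
        heads.append(att.matmul(H))
    out = heads[0] if len(heads) == 1 else concat(heads, axis=-1)
    out = out + pt[f"gat{layer}_b"]
    return out.elu()


def forward(
    x: np.ndarray,
    graph: CoexpressionGraph,
    params: dict[str, np.ndarray] | dict[str, Tensor],
    config: MLAGNNConfig,
    dropout_rng: np.random.Generator | None = None,
    track_input: bool = False,
) -> tuple[Tensor, LevelFeatures]:
    """Forward pass for a batch ``x`` of shape (B, n_genes, in_channels).

    Returns (logits, level features).  ``track_input`` marks G1 as a
    gradient leaf so saliency can read d(logit)/d(G1).
    """
    if x.ndim == 2:
        x = x[None]
    n_genes = graph.A.shape[0]
    if x.shape[1] != n_genes or x.shape[2] != config.in_channels:
        raise ValueError(
            f"G1 shape mismatch: got {x.shape[1:]}, graph has {n_genes} genes "
            f"and config expects {config.in_channels} channels"
        )
    if (graph.A.diagonal() == 0).any():
        raise ValueError("adjacency must contain self-loops (diagonal 1)")
    pt = params if isinstance(next(iter(params.values())), Tensor) else _as_tensors(params)
    mask_add = np.where(graph.A > 0, 0.0, MASK_NEG)

    attention: list[np.ndarray] = []
    G1 = Tensor(x, requires_grad=track_input)
    G2 = gat_layer(G1, mask_add, pt, 1, config, attention)
    G3 = gat_layer(G2, mask_add, pt, 2, config, attention)
    G2p = G2.matmul(pt["proj2_W"]) + pt["proj2_b"]
    G3p = G3.matmul(pt["proj3_W"]) + pt["proj3_b"]

    B = x.shape[0]
    F1 = G1.reshape(B, n_genes * config.in_channels)
    F2 = G2p.reshape(B, n_genes * config.projection_dim)
    F3 = G3p.reshape(B, n_genes * config.projection_dim)
    F = concat([F1, F2, F3], axis=1)

    Fd = F
    if dropout_rng is not None and config.dropout > 0:
        keep = (dropout_rng.random(F.shape) >= config.dropout) / (1 - config.dropout)
        Fd = mul_const(F, keep)
    logits = Fd.matmul(pt["head_W"]) + pt["head_b"]
    levels = LevelFeatures(
        G1=G1, G2=G2, G3=G3, G2p=G2p, G3p=G3p,
        F1=F1, F2=F2, F3=F3, F=F, attention=attention,
    )
    return logits, levels


def predict_proba(
    x: np.ndarray,
    graph: CoexpressionGraph,
    params: dict[str, np.ndarray],
    config: MLAGNNConfig,
    batch_size: int = 256,
) -> np.ndarray:
    """Tumor-class probability per sample (softmax of the logits)."""
    probs = []
    for lo in range(0, len(x), batch_size):
        logits, _ = forward(x[lo : lo + batch_size], graph, params, config)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs.append((e / e.sum(axis=1, keepdims=True))[:, 1])
    return np.concatenate(probs)


# -- training -----------------------------------------------------------------


def _class_weights(y: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return np.ones(len(y))
    counts = np.bincount(y, minlength=2).astype(float)
    w = len(y) / (2.0 * counts)
    return w[y]


def train(
    train_ds: IntegratedDataset,
    graph: CoexpressionGraph,
    config: MLAGNNConfig,
    val_ds: IntegratedDataset | None = None,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Adam on weighted cross-entropy; returns (params, per-epoch loss trace).

    All randomness (init, shuffling, dropout) is derived from config.seed.
    Early stopping monitors validation loss when a validation set is given.
    """
    if len(train_ds) == 0:
        raise ValueError("training set is empty")
    x, y = train_ds.features, train_ds.y
    params = init_params(config, len(train_ds.gene_ids))
    w = _class_weights(y, config.class_weighting)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    dropout_rng = np.random.default_rng(config.seed + 2)

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    trace: list[float] = []
    best_val, best_params, bad_epochs = np.inf, None, 0

    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(x))
        losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            pt = _as_tensors(params)
            logits, _ = forward(
                x[idx], graph, pt, config, dropout_rng=dropout_rng
            )
            loss = cross_entropy_with_logits(logits, y[idx], w[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            loss.backward()
            step += 1
            for k in params:
                g = pt[k].grad
                if g is None:
                    continue
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                params[k] = params[k] - config.learning_rate * mhat / (
                    np.sqrt(vhat) + eps
                )
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))

        if val_ds is not None and len(val_ds) > 0:
            vlogits, _ = forward(val_ds.features, graph, params, config)
            vloss = float(
                cross_entropy_with_logits(
                    Tensor(vlogits.data), val_ds.y,
                    _class_weights(val_ds.y, config.class_weighting),
                ).data
            )
            if vloss < best_val - 1e-6:
                best_val, bad_epochs = vloss, 0
                best_params = {k: p.copy() for k, p in params.items()}
            else:
                bad_epochs += 1
                if bad_epochs >= config.patience:
                    logger.info("early stop at epoch %d (val loss %.4f)", epoch, best_val)
                    return best_params, trace
    if best_params is not None and best_val < np.inf:
        return best_params, trace
    return params, trace


# -- full-gradient saliency ---------------------------------------------------


def fgs_saliency(
    params: dict[str, np.ndarray],
    graph: CoexpressionGraph,
    samples: np.ndarray,
    config: MLAGNNConfig,
    top_k: int = 10,
    include_bias: bool = True,
    batch_size: int = 256,
) -> SaliencyReport:
    """Rank genes by full-gradient attribution of the predicted-class logit.

    For every sample the gradient of its predicted-class logit is taken with
    respect to the level features G1 (-> F1), G2' (-> F2) and G3' (-> F3);
    per-node attributions are feature x gradient summed over the node's
    coordinates, plus (optionally) the producing layer's bias x gradient.
    The fused-F attribution is the sum of the three levels.  Per-gene scores
    are mean absolute attributions over samples.
    """
    if samples.ndim != 3 or len(samples) == 0:
        raise ValueError("need a non-empty (samples, genes, channels) array")
    for k_, p_ in params.items():
        if not np.all(np.isfinite(p_)):
            raise ValueError(f"non-finite parameter {k_!r}; train the model first")
    n_genes = len(graph.gene_ids)
    if top_k > n_genes:
        raise ValueError("top_k exceeds the number of genes")

    per_level_abs = {lvl: [] for lvl in ("F1", "F2", "F3", "F")}
    for lo in range(0, len(samples), batch_size):
        batch = samples[lo : lo + batch_size]
        pt = _as_tensors(params)
        logits, levels = forward(batch, graph, pt, config, track_input=True)
        pred = logits.data.argmax(axis=1)
        onehot = np.zeros_like(logits.data)
        onehot[np.arange(len(pred)), pred] = 1.0
        mul_const(logits, onehot).sum().backward()

        node_attr = {}
        for lvl, tensor, bias in (
            ("F1", levels.G1, None),
            ("F2", levels.G2p, params["proj2_b"]),
            ("F3", levels.G3p, params["proj3_b"]),
        ):
            grad = tensor.grad
            s = (tensor.data * grad).sum(axis=2)  # (B, N)
            if include_bias and bias is not None:
                s = s + (bias[None, None, :] * grad).sum(axis=2)
            node_attr[lvl] = s
        node_attr["F"] = node_attr["F1"] + node_attr["F2"] + node_attr["F3"]
        for lvl, s in node_attr.items():
            per_level_abs[lvl].append(np.abs(s))

    scores = pd.DataFrame(index=pd.Index(graph.gene_ids, name="gene_id"))
    for lvl in ("F1", "F2", "F3", "F"):
        scores[f"score_{lvl}"] = np.concatenate(per_level_abs[lvl]).mean(axis=0)
    order_f = scores["score_F"].to_numpy().argsort()[::-1]
    rank = np.empty(n_genes, dtype=int)
    rank[order_f] = np.arange(1, n_genes + 1)
    scores["rank_F"] = rank
    top = {
        lvl: list(
            scores[f"score_{lvl}"].sort_values(ascending=False).index[:top_k]
        )
        for lvl in ("F1", "F2", "F3", "F")
    }
    return SaliencyReport(scores=scores, top=top)
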