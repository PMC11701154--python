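"""Classification metrics and the baseline-classifier comparison harness.

The harness mirrors a standard tabular comparison: the attention model is
judged against a linear-kernel SVM (C = 1), Gaussian naive Bayes, a small
fully connected network (lr = 0.02, dropout = 0.6) and a 500-tree random
forest, all on the same flattened pair features, with tumor as the positive
class and AUROC computed by the rank (Mann-Whitney) statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .autodiff import Tensor, cross_entropy_with_logits, mul_const

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1_score: float
    auroc: float
    tn: int
    fp: int
    fn: int
    tp: int
    positive_class: str = "tumor"

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1_score": self.f1_score,
            "auroc": self.auroc,
            "confusion": {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp},
        }


def compute_metrics(scores: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """Hard metrics at threshold 0.5 plus rank-statistic AUROC.

    ``scores`` are tumor probabilities in [0,1]; ``labels`` integer
    (tumor = 1).  Single-class label vectors are rejected (AUROC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must be probabilities in [0,1]")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    pred = (scores > 0.5).astype(int)
    tn, fp, fn, tp = confusion_matrix(labels, pred, labels=[0, 1]).ravel()
    return MetricsReport(
        accuracy=float(accuracy_score(labels, pred)),
        precision=float(precision_score(labels, pred, zero_division=0)),
        recall=float(recall_score(labels, pred, zero_division=0)),
        f1_score=float(f1_score(labels, pred, zero_division=0)),
        auroc=float(roc_auc_score(labels, scores)),
        tn=int(tn), fp=int(fp), fn=int(fn), tp=int(tp),
    )


class DenseNet:
    """Small fully connected classifier with dropout, trained with Adam."""

    def __init__(
        self,
        hidden: int = 32,
        learning_rate: float = 0.02,
        dropout: float = 0.6,
        epochs: int = 40,
        batch_size: int = 64,
        seed: int = 0,
    ):
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.params: dict[str, np.ndarray] | None = None

    def _forward(self, x: np.ndarray, pt: dict, rng=None) -> Tensor:
        h = (Tensor(x).matmul(pt["W1"]) + pt["b1"]).leaky_relu(0.0)
        if rng is not None and self.dropout > 0:
            keep = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
            h = mul_const(h, keep)
        return h.matmul(pt["W2"]) + pt["b2"]

    def fit(self, x: np.ndarray, y: np.ndarray) -> "DenseNet":
        rng = np.random.default_rng(self.seed)
        d = x.shape[1]
        lim1 = np.sqrt(6.0 / (d + self.hidden))
        lim2 = np.sqrt(6.0 / (self.hidden + 2))
        params = {
            "W1": rng.uniform(-lim1, lim1, (d, self.hidden)),
            "b1": np.zeros(self.hidden),
            "W2": rng.uniform(-lim2, lim2, (self.hidden, 2)),
            "b2": np.zeros(2),
        }
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v) for k, v in params.items()}
        b1, b2, eps, step = 0.9, 0.999, 1e-8, 0
        drop_rng = np.random.default_rng(self.seed + 1)
        for _ in range(self.epochs):
            order = rng.permutation(len(x))
            for lo in range(0, len(order), self.batch_size):
                idx = order[lo : lo + self.batch_size]
                pt = {k: Tensor(p, requires_grad=True) for k, p in params.items()}
                loss = cross_entropy_with_logits(
                    self._forward(x[idx], pt, drop_rng), y[idx]
                )
                loss.backward()
                step += 1
                for k in params:
                    g = pt[k].grad
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g * g
                    params[k] -= self.learning_rate * (m[k] / (1 - b1**step)) / (
                        np.sqrt(v[k] / (1 - b2**step)) + eps
                    )
        self.params = params
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        pt = {k: Tensor(p) for k, p in self.params.items()}
        z = self._forward(x, pt).data
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def default_baselines(seed: int = 0) -> dict[str, object]:
    return {
        "SVM": SVC(kernel="linear", C=1.0, probability=True, random_state=seed),
        "NB": GaussianNB(),
        "DNN": DenseNet(learning_rate=0.02, dropout=0.6, seed=seed),
        "RF": RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1),
    }


def run_baselines(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    test_y: np.ndarray,
    baselines: dict[str, object] | None = None,
    seed: int = 0,
) -> dict[str, MetricsReport | None]:
    """Fit every baseline on flattened pair features and score the test set.

    Failures are isolated per baseline (reported as None); the harness
    continues.
    """
    if train_x.ndim == 3:
        train_x = train_x.reshape(len(train_x), -1)
        test_x = test_x.reshape(len(test_x), -1)
    if baselines is None:
        baselines = default_baselines(seed)
    out: dict[str, MetricsReport | None] = {}
    for name, clf in baselines.items():
        try:
            clf.fit(train_x, train_y)
            prob = clf.predict_proba(test_x)[:, 1]
            out[name] = compute_metrics(prob, test_y)
        except Exception as exc:
            logger.warning("baseline %s failed: %s", name, exc)
            out[name] = None
    return out
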