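"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the attention network needs: broadcast
arithmetic, batched matrix products, reshape/concat, leaky ReLU and ELU,
a numerically stable softmax over the last axis, and a weighted
cross-entropy head.  Gradients of any intermediate tensor are retained
after ``backward``, which is what the full-gradient saliency machinery
reads (gradients at the level features, not only at the leaves).

The engine is deliberately small; every operator's vector-Jacobian product
is written explicitly and checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape entry that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _child(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        def backward(g):
            return (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            )

        return self._mk2(other, self.data + other.data, backward)

    def __sub__(self, other: "Tensor") -> "Tensor":
        def backward(g):
            return (
                _unbroadcast(g, self.shape),
                _unbroadcast(-g, other.shape),
            )

        return self._mk2(other, self.data - other.data, backward)

    def __mul__(self, other: "Tensor") -> "Tensor":
        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._mk2(other, self.data * other.data, backward)

    def _mk2(self, other: "Tensor", data, backward) -> "Tensor":
        out = Tensor(data)
        if self.requires_grad or other.requires_grad:
            out.requires_grad = True
            parents, picks = [], []
            for i, p in enumerate((self, other)):
                if p.requires_grad:
                    parents.append(p)
                    picks.append(i)
            out._parents = tuple(parents)
            out._backward = lambda g: tuple(backward(g)[i] for i in picks)
        return out

    def scale(self, c: float) -> "Tensor":
        return self._child(self.data * c, (self,), lambda g: (g * c,))

    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matmul: (..., n, m) @ (..., m, k) with broadcasting."""

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (
                _unbroadcast(ga, self.shape),
                _unbroadcast(gb, other.shape),
            )

        return self._mk2(other, self.data @ other.data, backward)

    def transpose_last(self) -> "Tensor":
        return self._child(
            np.swapaxes(self.data, -1, -2),
            (self,),
            lambda g: (np.swapaxes(g, -1, -2),),
        )

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        old = self.shape
        return self._child(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def sum(self, axis=None) -> "Tensor":
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            return (np.broadcast_to(np.expand_dims(g, axis), self.shape).copy(),)

        return self._child(self.data.sum(axis=axis), (self,), backward)

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis).scale(1.0 / n)

    # -- nonlinearities -------------------------------------------------------

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)
        return self._child(self.data * mask, (self,), lambda g: (g * mask,))

    def elu(self) -> "Tensor":
        pos = self.data > 0
        out_data = np.where(pos, self.data, np.expm1(self.data))
        deriv = np.where(pos, 1.0, out_data + 1.0)
        return self._child(out_data, (self,), lambda g: (g * deriv,))

    def softmax_last(self) -> "Tensor":
        """Softmax over the last axis (stable; use additive masks upstream)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=-1, keepdims=True)
            return (s * (g - dot),)

        return self._child(s, (self,), backward)

    # -- autodiff driver ------------------------------------------------------

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. the whole tape."""
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad = parent.grad + g


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]
        parents = [t for t in tensors if t.requires_grad]
        keep = [i for i, t in enumerate(tensors) if t.requires_grad]

        def backward(g):
            parts = np.split(g, splits, axis=axis)
            return tuple(parts[i] for i in keep)

        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def add_const(t: Tensor, c: np.ndarray) -> Tensor:
    return t._child(t.data + c, (t,), lambda g: (_unbroadcast(g, t.shape),))


def mul_const(t: Tensor, c: np.ndarray) -> Tensor:
    c = np.asarray(c, dtype=np.float64)
    return t._child(t.data * c, (t,), lambda g: (_unbroadcast(g * c, t.shape),))


def cross_entropy_with_logits(
    logits: Tensor, y: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """Mean weighted cross-entropy.  ``logits`` (B, C); ``y`` integer labels.

    Gradient is the classic (softmax - onehot) * weight / sum(weight).
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    b = np.arange(len(y))
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=np.float64)
    loss = -(w * logp[b, y]).sum() / w.sum()

    def backward(g):
        p = np.exp(logp)
        p[b, y] -= 1.0
        return (g * p * (w / w.sum())[:, None],)

    return logits._child(np.asarray(loss), (logits,), backward)
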