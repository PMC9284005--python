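"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the LSTM / CNN / attention network on CPU:
a :class:`Tensor` wrapping an ``ndarray``, elementwise ops with broadcasting,
matmul, reshapes/slicing/concat, the nonlinearities the model needs, and a
handful of fused structured ops (patch gathering for convolution, segment
pooling for channel attention, weighted softmax cross-entropy).

Gradients accumulate into ``Tensor.grad`` after calling ``backward()`` on a
scalar. Only tensors created with ``requires_grad=True`` (parameters) or
depending on one keep a graph.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    # ---- graph traversal ----
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # ---- operator sugar ----
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad g down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---- primitive ops ----

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g @ b.data.swapaxes(-1, -2))
        if b.requires_grad:
            gb = a.data.swapaxes(-1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def bwd(g):
        a._accum(g.reshape(a.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def transpose(a: Tensor, axes) -> Tensor:
    out = Tensor(a.data.transpose(axes), parents=(a,))
    inv = np.argsort(axes)

    def bwd(g):
        a._accum(g.transpose(inv))

    out._backward = bwd if out.requires_grad else None
    return out


def _is_basic_key(key) -> bool:
    parts = key if isinstance(key, tuple) else (key,)
    return all(isinstance(p, (int, np.integer, slice)) for p in parts)


def getitem(a: Tensor, key) -> Tensor:
    out = Tensor(a.data[key], parents=(a,))
    basic = _is_basic_key(key)  # basic indexing never aliases -> plain += is safe

    def bwd(g):
        full = np.zeros_like(a.data)
        if basic:
            full[key] += g
        else:
            np.add.at(full, key, g)
        a._accum(full)

    out._backward = bwd if out.requires_grad else None
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out._backward = bwd if out.requires_grad else None
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def bwd(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), _wrap(1.0 / n))


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    out = Tensor(y, parents=(a,))

    def bwd(g):
        a._accum(g * y * (1 - y))

    out._backward = bwd if out.requires_grad else None
    return out


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, parents=(a,))

    def bwd(g):
        a._accum(g * (1 - y * y))

    out._backward = bwd if out.requires_grad else None
    return out


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    x = a.data
    neg = alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
    y = np.where(x > 0, x, neg)
    out = Tensor(y, parents=(a,))

    def bwd(g):
        a._accum(g * np.where(x > 0, 1.0, neg + alpha))

    out._backward = bwd if out.requires_grad else None
    return out


def power(a: Tensor, exponent: float) -> Tensor:
    y = a.data**exponent
    out = Tensor(y, parents=(a,))

    def bwd(g):
        a._accum(g * exponent * a.data ** (exponent - 1))

    out._backward = bwd if out.requires_grad else None
    return out


def dropout(a: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, _wrap(mask))


# ---- structured ops ----

def gather_patches(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather sliding patches along the last axis: (N, C, L) -> (N, C, L_out, K).

    ``idx`` is an integer (L_out, K) matrix of source sample indices
    (reflect-padded indices precomputed by the caller).
    """
    out = Tensor(a.data[..., idx], parents=(a,))

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full.reshape(-1, a.data.shape[-1]), (slice(None), idx.ravel()),
                  g.reshape(-1, idx.size))
        a._accum(full)

    out._backward = bwd if out.requires_grad else None
    return out


def segment_mean(a: Tensor, starts: np.ndarray, sizes: np.ndarray) -> Tensor:
    """Mean over contiguous segments of the last axis: (N, D) -> (N, G)."""
    y = np.add.reduceat(a.data, starts, axis=-1) / sizes
    out = Tensor(y, parents=(a,))

    def bwd(g):
        a._accum(np.repeat(g / sizes, sizes, axis=-1))

    out._backward = bwd if out.requires_grad else None
    return out


def segment_max(a: Tensor, starts: np.ndarray, sizes: np.ndarray) -> Tensor:
    """Max over contiguous segments of the last axis; ties share gradient."""
    y = np.maximum.reduceat(a.data, starts, axis=-1)
    expanded = np.repeat(y, sizes, axis=-1)
    mask = (a.data == expanded).astype(float)
    ties = np.repeat(np.add.reduceat(mask, starts, axis=-1), sizes, axis=-1)
    out = Tensor(y, parents=(a,))

    def bwd(g):
        a._accum(np.repeat(g, sizes, axis=-1) * mask / ties)

    out._backward = bwd if out.requires_grad else None
    return out


def segment_scale(a: Tensor, w: Tensor, sizes: np.ndarray) -> Tensor:
    """Multiply each contiguous segment of ``a`` by its scalar weight in ``w``."""
    wexp = np.repeat(w.data, sizes, axis=-1)
    out = Tensor(a.data * wexp, parents=(a, w))
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    def bwd(g):
        if a.requires_grad:
            a._accum(g * wexp)
        if w.requires_grad:
            w._accum(np.add.reduceat(g * a.data, starts, axis=-1))

    out._backward = bwd if out.requires_grad else None
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits: Tensor, labels: np.ndarray, class_weights: np.ndarray) -> Tensor:
    """Mean class-weighted categorical cross-entropy over a batch.

    ``loss = sum_i w_{y_i} * (-log p_{i, y_i}) / sum_i w_{y_i}``.
    """
    n = logits.data.shape[0]
    p = softmax(logits.data)
    wi = class_weights[labels]
    wsum = wi.sum()
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-300))
    out = Tensor((wi * nll).sum() / wsum, parents=(logits,))

    def bwd(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accum(g * grad * (wi / wsum)[:, None])

    out._backward = bwd if out.requires_grad else None
    return out
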