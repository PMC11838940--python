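"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core backing the transformer model: a small tape-based
autodiff engine with exactly the operations a post-norm transformer encoder
needs (broadcast arithmetic, batched matmul, softmax, layer norm, GELU,
masked attention, gather-style pooling, cross-entropy).  Gradients are
accumulated in ``Tensor.grad`` by :meth:`Tensor.backward`, which performs a
topological sweep of the recorded graph.

All arrays are float64.  Every operation's backward pass is exercised against
central finite differences in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "sum_",
    "mean_",
    "softmax",
    "layer_norm",
    "gelu",
    "relu",
    "gather_rows",
    "cross_entropy_logits",
    "scale",
    "add_const",
    "dropout",
]


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor; defaults to d(self)/d(self)=1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for long sequences
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = parents
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(-g, b.data.shape))

    return _make(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        a._accumulate(g * c)

    return _make(a.data * c, (a,), backward)


def add_const(a: Tensor, c) -> Tensor:
    """Add a constant array (no gradient flows into ``c``)."""
    c = np.asarray(c, dtype=np.float64)

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))

    return _make(a.data + c, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product ``a @ b`` with broadcast-aware gradients."""

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(np.matmul(a.data, b.data), (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(np.transpose(g, inv))

    return _make(np.transpose(a.data, axes), (a,), backward)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return scale(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accumulate(y * (g - dot))

    return _make(y, (a,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    n = x.data.shape[-1]

    def backward(g):
        red = tuple(range(g.ndim - 1))
        gamma._accumulate((g * xhat).sum(axis=red))
        beta._accumulate(g.sum(axis=red))
        dxhat = g * gamma.data
        dx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True) / n
        )
        x._accumulate(dx)

    return _make(xhat * gamma.data + beta.data, (x, gamma, beta), backward)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian Error Linear Unit."""
    from scipy.special import erf

    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data * x.data)
        x._accumulate(g * (cdf + x.data * pdf))

    return _make(x.data * cdf, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return _make(x.data * mask, (x,), backward)


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select one sequence position per batch element: (B,S,D),(B,) -> (B,D)."""
    index = np.asarray(index, dtype=np.intp)
    batch = np.arange(x.data.shape[0])

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[batch, index] = g
        x._accumulate(gx)

    return _make(x.data[batch, index], (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    """Inverted dropout; identity when ``p == 0`` or not training."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)

    def backward(g):
        x._accumulate(g * keep)

    return _make(x.data * keep, (x,), backward)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under a softmax over logits."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(g * p / n)

    return _make(np.asarray(loss), (logits,), backward)
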