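"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical substrate for the GVP network: a tape of ``Tensor``
nodes, each holding a float64 array and a closure that routes the upstream
gradient to its parents. Only the operations the network needs are provided
(elementwise arithmetic with broadcasting, matmul, a vector-channel matmul,
gather/scatter for message passing, reductions, relu/sigmoid/sqrt and a
guarded row-norm). Gradients are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "add",
    "sub",
    "mul",
    "div",
    "matmul",
    "vecmat",
    "take",
    "segment_sum",
    "concat",
    "reshape",
    "relu",
    "sigmoid",
    "sqrt",
    "tsum",
    "tmean",
    "safe_norm",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the block (used for eval-mode scoring)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the incoming array may be a view of another grad
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    if _grad_enabled and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True,
                      parents=tuple(parents), backward=backward)
    return Tensor(data)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product ``a @ b``."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def _channel_mix(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    # (n, ci, 3) x (ci, co) -> (n, co, 3) via one BLAS gemm
    n, ci, _ = V.shape
    if n == 0:
        return np.zeros((0, W.shape[1], 3))
    out = (V.transpose(0, 2, 1).reshape(n * 3, ci) @ W)
    return out.reshape(n, 3, W.shape[1]).transpose(0, 2, 1)


def vecmat(V: Tensor, W: Tensor) -> Tensor:
    """Channel-mixing matmul on a vector feature array.

    V has shape (n, v_in, 3); W has shape (v_in, v_out); the result is
    (n, v_out, 3). This mixes vector channels without touching the spatial
    axis, so rotation equivariance of the 3-axis is preserved exactly.
    """
    V, W = as_tensor(V), as_tensor(W)
    out_data = _channel_mix(V.data, W.data)

    def backward(g):
        if V.requires_grad:
            V._accumulate(_channel_mix(g, W.data.T))
        if W.requires_grad:
            n, ci, _ = V.shape
            Vm = V.data.transpose(0, 2, 1).reshape(n * 3, ci)
            gm = g.transpose(0, 2, 1).reshape(n * 3, -1)
            W._accumulate(Vm.T @ gm)

    return _make(out_data, (V, W), backward)


def _scatter_rows(rows: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Sum ``rows`` (m, ...) into ``n`` bins by ``idx``; bincount per column
    is much faster than ``np.add.at`` for wide feature arrays."""
    flat = rows.reshape(rows.shape[0], -1)
    out = np.empty((n, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.bincount(idx, weights=flat[:, c], minlength=n)
    return out.reshape((n,) + rows.shape[1:])


def take(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows ``a[idx]`` along the first axis."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            a._accumulate(_scatter_rows(g, idx, a.shape[0]))

    return _make(out_data, (a,), backward)


def segment_sum(a: Tensor, idx: np.ndarray, num_segments: int) -> Tensor:
    """Scatter-add rows of ``a`` into ``num_segments`` bins given by ``idx``."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = _scatter_rows(a.data, idx, num_segments)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[idx])

    return _make(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(ts), backward)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * 0.5 / np.maximum(out_data, 1e-12))

    return _make(out_data, (a,), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    count = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / count))


def safe_norm(V: Tensor, axis: int = -1, keepdims: bool = False,
              eps: float = 1e-8) -> Tensor:
    """Euclidean norm along ``axis``, exact in the forward pass.

    The backward pass guards the division so that zero vectors get a zero
    (sub)gradient instead of NaN; this keeps the all-zero vector channel of
    freshly embedded nodes well behaved.
    """
    V = as_tensor(V)
    norm = np.sqrt((V.data ** 2).sum(axis=axis, keepdims=True))
    out_data = norm if keepdims else np.squeeze(norm, axis=axis)

    def backward(g):
        if V.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axis)
            V._accumulate(gg * V.data / np.maximum(norm, eps))

    return _make(out_data, (V,), backward)
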