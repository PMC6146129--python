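"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the taggers and classifiers in this package
need: broadcast arithmetic, matmul, pointwise nonlinearities, embedding
lookup (gather with scatter-add gradient), sliding-window extraction for 1-D
convolution, max-over-axis pooling, concatenation, reshape, dropout and a
fused softmax cross-entropy. Everything is float64 and CPU-only; graphs are
built eagerly and freed after ``backward``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "constant", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- graph -------------------------------------------------------------

    def backward(self) -> None:
        topo = _topo_order(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # free graph references
        for t in topo:
            t._parents = ()
            t._backward = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- operator sugar ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __add__(self, other): return add(self, _as_tensor(other))
    def __radd__(self, other): return add(_as_tensor(other), self)
    def __sub__(self, other): return add(self, mul(_as_tensor(other), constant(-1.0)))
    def __mul__(self, other): return mul(self, _as_tensor(other))
    def __rmul__(self, other): return mul(_as_tensor(other), self)
    def __matmul__(self, other): return matmul(self, other)
    def __neg__(self): return mul(self, constant(-1.0))


def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in visited or not node.requires_grad:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))
    return order


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


# ---------------------------------------------------------------------------
# Arithmetic


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D (or batched-leading) matrix product a @ b with b 2-D."""
    out_data = a.data @ b.data

    def bw(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            ga = a.data.reshape(-1, a.data.shape[-1]).T @ g.reshape(-1, g.shape[-1])
            b._accumulate(ga)

    return Tensor(out_data, parents=(a, b), backward=bw)


# ---------------------------------------------------------------------------
# Nonlinearities


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def bw(g: np.ndarray) -> None:
        x._accumulate(g * (x.data > 0))

    return Tensor(out_data, parents=(x,), backward=bw)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def bw(g: np.ndarray) -> None:
        x._accumulate(g * (1.0 - out_data**2))

    return Tensor(out_data, parents=(x,), backward=bw)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bw(g: np.ndarray) -> None:
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=bw)


# ---------------------------------------------------------------------------
# Structure


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(s, e)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out_data = x.data.reshape(shape)

    def bw(g: np.ndarray) -> None:
        x._accumulate(g.reshape(x.data.shape))

    return Tensor(out_data, parents=(x,), backward=bw)


def take(table: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup: rows of ``table`` at integer array ``idx``.

    Output shape = idx.shape + (table.shape[1],); gradient scatter-adds.
    """
    idx = np.asarray(idx)
    out_data = table.data[idx]

    def bw(g: np.ndarray) -> None:
        gt = np.zeros_like(table.data)
        np.add.at(gt, idx.reshape(-1), g.reshape(-1, table.data.shape[1]))
        table._accumulate(gt)

    return Tensor(out_data, parents=(table,), backward=bw)


def windows(x: Tensor, size: int) -> Tensor:
    """Sliding windows along axis 1 of a (B, L, D) tensor, flattened:
    output (B, L - size + 1, size * D). Used as im2col for 1-D convolution."""
    B, L, D = x.data.shape
    n = L - size + 1
    if n < 1:
        raise ValueError(f"sequence length {L} shorter than window {size}")
    view = np.lib.stride_tricks.sliding_window_view(x.data, (size,), axis=1)
    # view: (B, n, D, size) -> (B, n, size, D)
    out_data = np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(B, n, size * D)

    def bw(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        gw = g.reshape(B, n, size, D)
        for j in range(size):
            gx[:, j : j + n, :] += gw[:, :, j, :]
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=bw)


def amax(x: Tensor, axis: int) -> Tensor:
    """Max over one axis; gradient flows to the first argmax position."""
    out_data = x.data.max(axis=axis)
    arg = x.data.argmax(axis=axis)

    def bw(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        np.put_along_axis(
            gx, np.expand_dims(arg, axis), np.expand_dims(g, axis), axis
        )
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=bw)


def select_step(x: Tensor, i: int) -> Tensor:
    """x[:, i, :] for a (B, L, D) tensor."""
    out_data = x.data[:, i, :]

    def bw(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        gx[:, i, :] = g
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=bw)


def slice_cols(x: Tensor, a: int, b: int) -> Tensor:
    out_data = x.data[:, a:b]

    def bw(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        gx[:, a:b] = g
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only during training."""
    if rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep
    return mul(x, constant(mask))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Per-row cross-entropy of softmax(logits) against integer labels.

    logits: (N, m); labels: (N,) ints. Returns a (N,) tensor of losses.
    Numerically stable (max subtraction).
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = np.arange(labels.shape[0])
    out_data = -np.log(probs[n, labels])

    def bw(g: np.ndarray) -> None:
        gl = probs.copy()
        gl[n, labels] -= 1.0
        logits._accumulate(gl * g[:, None])

    return Tensor(out_data, parents=(logits,), backward=bw)


def sum_(x: Tensor) -> Tensor:
    out_data = np.asarray(x.data.sum())

    def bw(g: np.ndarray) -> None:
        x._accumulate(np.broadcast_to(g, x.data.shape).astype(np.float64))

    return Tensor(out_data, parents=(x,), backward=bw)


def softmax(q: np.ndarray) -> np.ndarray:
    """Plain-NumPy softmax along the last axis (inference path); subtracts the
    max before exponentiation for stability."""
    z = q - q.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
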