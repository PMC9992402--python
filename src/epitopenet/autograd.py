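"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is a small, self-contained define-by-run engine providing exactly the
operations the epitope classifier needs: broadcasting arithmetic, matrix
multiplication, the sigmoid/tanh/ReLU nonlinearities, softmax, axis
reductions, slicing/stacking/concatenation, embedding lookup, 'same'-padded
1-D convolution, max pooling, dropout and a numerically stable binary
cross-entropy on logits.  Gradients are accumulated by a topological-order
sweep over the recorded graph.

All computation is float64 NumPy; given seeded initial weights and a seeded
data order, training is bit-reproducible on a single machine.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, other: "Tensor") -> "Tensor":
        return mul(self, other)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        return matmul(self, other)

    def reshape(self, *shape: int) -> "Tensor":
        return reshape(self, shape)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data, parents=parents)
    if out.requires_grad:
        out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product."""
    out_data = a.data @ b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def reshape(x: Tensor, shape: Sequence[int]) -> Tensor:
    old_shape = x.shape

    def backward(g: np.ndarray) -> None:
        x._accumulate(g.reshape(old_shape))

    return _make(x.data.reshape(shape), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # stable piecewise sigmoid
    pos = x.data >= 0
    s = np.empty_like(x.data)
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    s[~pos] = ex / (1.0 + ex)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * (1.0 - t * t))

    return _make(t, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return _make(x.data * mask, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray) -> None:
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return _make(s, (x,), backward)


def sum_along(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: np.ndarray) -> None:
        gg = g if keepdims else np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(gg, x.shape).copy())

    return _make(out_data, (x,), backward)


def mean_all(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g: np.ndarray) -> None:
        x._accumulate(np.full(x.shape, float(g) / n))

    return _make(x.data.mean(), (x,), backward)


def max_along(x: Tensor, axis: int) -> Tensor:
    """Max reduction; gradient flows to the (first) argmax only."""
    out_data = x.data.max(axis=axis)
    argmax = x.data.argmax(axis=axis)

    def backward(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        idx = list(np.indices(out_data.shape))
        idx.insert(axis % x.data.ndim, argmax)
        gx[tuple(idx)] = g
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g: np.ndarray) -> None:
        parts = np.moveaxis(g, axis, 0)
        for t, gi in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(gi)

    return _make(out_data, tuple(tensors), backward)


def slice_axis1(x: Tensor, start: int, stop: int) -> Tensor:
    """x[:, start:stop] for a 2-D or 3-D tensor."""
    out_data = x.data[:, start:stop]

    def backward(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        gx[:, start:stop] = g
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def timestep(x: Tensor, t: int) -> Tensor:
    """x[:, t, :] from an (n, T, D) tensor."""
    out_data = x.data[:, t, :]

    def backward(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        gx[:, t, :] = g
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup: (V, E) weights gathered by an integer (n, L) index array."""
    indices = np.asarray(indices, dtype=np.int64)
    out_data = weight.data[indices]

    def backward(g: np.ndarray) -> None:
        gw = np.zeros_like(weight.data)
        np.add.at(gw, indices, g)
        weight._accumulate(gw)

    return _make(out_data, (weight,), backward)


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution along the sequence axis with 'same' zero padding.

    x: (n, L, C) activations, w: (k, C, F) kernel, b: (F,) bias -> (n, L, F).
    Stride 1; every kernel width k <= L sees all L positions.
    """
    n, L, C = x.shape
    k, _, F = w.shape
    left = (k - 1) // 2
    right = k - 1 - left
    xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    out_data = np.broadcast_to(b.data, (n, L, F)).copy()
    for j in range(k):
        out_data += xp[:, j : j + L, :] @ w.data[j]

    def backward(g: np.ndarray) -> None:
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            g2 = g.reshape(n * L, F)
            for j in range(k):
                patch = xp[:, j : j + L, :].reshape(n * L, C)
                gw[j] = patch.T @ g2
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, j : j + L, :] += g @ w.data[j].T
            x._accumulate(gxp[:, left : left + L, :])

    return _make(out_data, (x, w, b), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only during training."""
    if rate <= 0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return _make(x.data * mask, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    y = np.asarray(targets, dtype=np.float64).reshape(logits.shape)
    z = logits.data
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g: np.ndarray) -> None:
        p = np.empty_like(z)
        pos = z >= 0
        p[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        p[~pos] = ez / (1.0 + ez)
        logits._accumulate(float(g) * (p - y) / n)

    return _make(loss.mean(), (logits,), backward)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    __slots__ = ("name",)

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True)
        self.name = name


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
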