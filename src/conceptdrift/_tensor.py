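"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the model are implemented (affine maps,
gated-recurrent arithmetic, scaled dot-product attention, masked softmax,
binary cross-entropy with logits).  Everything is float64 and
single-threaded, which keeps seeded runs bit-reproducible.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "scatter_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        a, b = self, Tensor._wrap(other)

        def backward(g):
            return (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._wrap(other) + (-self)

    def __neg__(self) -> "Tensor":
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __mul__(self, other) -> "Tensor":
        a, b = self, Tensor._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            )

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar) -> "Tensor":
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by constants")
        return self * (1.0 / scalar)

    def __matmul__(self, other) -> "Tensor":
        a, b = self, Tensor._wrap(other)

        def backward(g):
            ga = _unbroadcast(np.matmul(g, b.data.swapaxes(-1, -2)), a.shape)
            gb = _unbroadcast(np.matmul(a.data.swapaxes(-1, -2), g), b.shape)
            return (ga, gb)

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        a = self
        old = a.shape
        return Tensor._make(a.data.reshape(*shape), (a,), lambda g: (g.reshape(old),))

    def transpose(self, *axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(*axes), (a,), lambda g: (g.transpose(*inv),)
        )

    def __getitem__(self, key) -> "Tensor":
        a = self

        def backward(g):
            ga = np.zeros_like(a.data)
            np.add.at(ga, key, g)
            return (ga,)

        return Tensor._make(a.data[key], (a,), backward)

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Advanced row indexing along axis 0 (gather)."""
        return self[np.asarray(idx)]

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- nonlinearities -------------------------------------------------------

    def sigmoid(self) -> "Tensor":
        a = self
        y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
        return Tensor._make(y, (a,), lambda g: (g * y * (1.0 - y),))

    def tanh(self) -> "Tensor":
        a = self
        y = np.tanh(a.data)
        return Tensor._make(y, (a,), lambda g: (g * (1.0 - y * y),))

    def cos(self) -> "Tensor":
        a = self
        return Tensor._make(np.cos(a.data), (a,), lambda g: (g * -np.sin(a.data),))

    def softplus(self) -> "Tensor":
        a = self
        y = np.logaddexp(0.0, a.data)
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
        return Tensor._make(y, (a,), lambda g: (g * s,))

    def softmax(self, axis: int = -1) -> "Tensor":
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        return Tensor._make(y, (a,), backward)

    # -- autograd driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)

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

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, backward)


def scatter_rows(base: np.ndarray, idx: np.ndarray, rows: Tensor) -> Tensor:
    """Constant matrix `base` with rows at `idx` replaced by `rows` (traced)."""
    idx = np.asarray(idx)
    rows = Tensor._wrap(rows)
    data = np.array(base, dtype=np.float64, copy=True)
    data[idx] = rows.data
    return Tensor._make(data, (rows,), lambda g: (g[idx],))
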