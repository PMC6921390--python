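"""Compact reverse-mode automatic differentiation over numpy arrays.

The models in this package are small (hidden sizes of tens to low hundreds,
visit sequences of length ~10), so a minimal tape-based engine over float64
numpy arrays is both fast enough and easy to verify: every primitive here is
covered by central-finite-difference tests.

Only the primitives the diagnosis-prediction models need are implemented:
elementwise arithmetic with broadcasting, matmul, the sigmoid/tanh/ReLU/exp/log
nonlinearities, reductions (sum / mean / max), a fused numerically-stable
softmax, concatenation / stacking / reshaping, and integer gather.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[Array], Sequence[Array | None]] | None = None
        self.name = name

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}{tag})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        """Accumulate gradients of this (scalar unless `grad` given) node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order by iterative DFS
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
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: Array, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._backward = backward
    return out


# -- primitives ---------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return _node(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires >=2-d operands; reshape first")
    data = a.data @ b.data

    def backward(g):
        ga = _unbroadcast(g @ b.data.swapaxes(-1, -2), a.shape)
        gb = _unbroadcast(a.data.swapaxes(-1, -2) @ g, b.shape)
        return ga, gb

    return _node(data, (a, b), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        return (g * (1.0 - data * data),)

    return _node(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # stable logistic
    data = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                    np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))

    def backward(g):
        return (g * data * (1.0 - data),)

    return _node(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        return (g * (a.data > 0),)

    return _node(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        return (g * data,)

    return _node(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        return (g / a.data,)

    return _node(data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside [lo, hi]."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)

    def backward(g):
        return (g * ((a.data >= lo) & (a.data <= hi)),)

    return _node(data, (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return _node(data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def tmax(a, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; gradient routed to the first argmax entry."""
    a = as_tensor(a)
    data = a.data.max(axis=axis, keepdims=keepdims)
    arg = a.data.argmax(axis=axis)

    def backward(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        out = np.zeros(a.shape)
        idx = list(np.indices(arg.shape))
        idx.insert(axis if axis >= 0 else a.ndim + axis, arg)
        np.add.at(out, tuple(idx), np.squeeze(g, axis=axis))
        return (out,)

    return _node(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stabilised softmax (max-subtraction) along `axis`."""
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        return (data * (g - dot),)

    return _node(data, (a,), backward)


def concatenate(parts: Iterable[Tensor], axis: int = 0) -> Tensor:
    parts = tuple(as_tensor(p) for p in parts)
    data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(data, parts, backward)


def stack(parts: Iterable[Tensor], axis: int = 0) -> Tensor:
    parts = tuple(as_tensor(p) for p in parts)
    data = np.stack([p.data for p in parts], axis=axis)

    def backward(g):
        return tuple(np.squeeze(piece, axis=axis)
                     for piece in np.split(g, len(parts), axis=axis))

    return _node(data, parts, backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        return (g.reshape(a.shape),)

    return _node(data, (a,), backward)


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = as_tensor(a)
    data = a.data.swapaxes(ax1, ax2)

    def backward(g):
        return (g.swapaxes(ax1, ax2),)

    return _node(data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    data = a.data[idx]
    parts = idx if isinstance(idx, tuple) else (idx,)
    fancy = any(isinstance(p, (np.ndarray, list)) for p in parts)

    def backward(g):
        out = np.zeros(a.shape)
        if fancy:  # indices may repeat
            np.add.at(out, idx, g)
        else:  # basic indexing never aliases
            out[idx] += g
        return (out,)

    return _node(data, (a,), backward)


def take(a, indices, axis: int = 0) -> Tensor:
    """Gather rows (or slices along `axis`) by an integer index array."""
    a = as_tensor(a)
    indices = np.asarray(indices)
    data = np.take(a.data, indices, axis=axis)

    def backward(g):
        out = np.zeros(a.shape)
        if axis == 0:
            np.add.at(out, indices, g)
        else:  # move the gathered axis to the front, scatter, move back
            np.add.at(np.moveaxis(out, axis, 0), indices, np.moveaxis(g, axis, 0))
        return (out,)

    return _node(data, (a,), backward)
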