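"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a
float64 numpy array and remembers how it was produced, so that
:meth:`Tensor.backward` can accumulate gradients by reverse topological
traversal.  Only the operations the score networks need are provided
(broadcasted arithmetic, batched matmul, reductions, concatenation,
reshaping, a few pointwise nonlinearities).  All computation is float64:
the equivariance contracts of the networks are asserted at 1e-5 relative
error and float32 round-off would eat most of that budget.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "layer_norm",
    "exp",
    "log",
    "sqrt",
    "sigmoid",
    "silu",
    "tanh",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable taping inside the block (pure inference, no graph built)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backward pass ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
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
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    # copy only if aliased: a view, or the output's own grad
                    # (an op may hand the incoming grad straight through)
                    if not pgrad.flags.owndata or pgrad is node.grad:
                        pgrad = pgrad.copy()
                    parent.grad = pgrad
                else:
                    parent.grad += pgrad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = tensor(other)
        out = self.data + other.data
        return Tensor._make(
            out,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = self.data * other.data
        return Tensor._make(
            out,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        out = self.data / other.data
        return Tensor._make(
            out,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self.data**exponent
        return Tensor._make(
            out,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = tensor(other)
        out = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (
                _unbroadcast(ga, self.shape),
                _unbroadcast(gb, other.shape),
            )

        return Tensor._make(out, (self, other), backward)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._make(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        return Tensor._make(
            np.transpose(self.data, axes), (self,), lambda g: (np.transpose(g, inv),)
        )

    def broadcast_to(self, shape):
        old = self.shape
        return Tensor._make(
            np.broadcast_to(self.data, shape).copy(),
            (self,),
            lambda g: (_unbroadcast(g, old),),
        )

    def __getitem__(self, idx):
        out = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out, (self,), backward)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, self.shape),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / count


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- pointwise functions ----------------------------------------------------


def exp(x: Tensor) -> Tensor:
    x = tensor(x)
    out = np.exp(x.data)
    return Tensor._make(out, (x,), lambda g: (g * out,))


def log(x: Tensor) -> Tensor:
    x = tensor(x)
    return Tensor._make(np.log(x.data), (x,), lambda g: (g / x.data,))


def sqrt(x: Tensor) -> Tensor:
    x = tensor(x)
    out = np.sqrt(x.data)
    return Tensor._make(out, (x,), lambda g: (g * 0.5 / out,))


def sigmoid(x: Tensor) -> Tensor:
    x = tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._make(out, (x,), lambda g: (g * out * (1.0 - out),))


def silu(x: Tensor) -> Tensor:
    x = tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = x.data * s
    return Tensor._make(out, (x,), lambda g: (g * (s * (1.0 + x.data * (1.0 - s))),))


def tanh(x: Tensor) -> Tensor:
    x = tensor(x)
    out = np.tanh(x.data)
    return Tensor._make(out, (x,), lambda g: (g * (1.0 - out**2),))


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Fused normalization over the trailing axis: (x - mu)/sd * gain + bias.

    One taped op with a closed-form backward instead of six elementwise ops.
    """
    x, gain, bias = tensor(x), tensor(gain), tensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    centered = x.data - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    inv_sd = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv_sd
    out = xhat * gain.data + bias.data

    def backward(g):
        dxhat = g * gain.data
        dx = inv_sd * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        axes = tuple(range(g.ndim - 1))
        return (dx, (g * xhat).sum(axis=axes), g.sum(axis=axes))

    return Tensor._make(out, (x, gain, bias), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tuple(tensors), backward)
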