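"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based autodiff core: enough to train the
residual-attention U-Nets in this package on CPU, nothing more.  Arrays are
float32 by default; the tape is only recorded while gradients are globally
enabled (see :func:`no_grad`) and at least one input requires them.
"""

from __future__ import annotations

import contextlib
from typing import Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def accumulate_grad(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=np.float32)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._prev:
            def _bw(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    a.accumulate_grad(_unbroadcast(g, a.shape))
                if b.requires_grad or b._prev:
                    b.accumulate_grad(_unbroadcast(g, b.shape))
            out._backward = _bw
        return out

    def __radd__(self, other):
        return self.__add__(other)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._prev:
            def _bw(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    a.accumulate_grad(_unbroadcast(g * b.data, a.shape))
                if b.requires_grad or b._prev:
                    b.accumulate_grad(_unbroadcast(g * a.data, b.shape))
            out._backward = _bw
        return out

    def __rmul__(self, other):
        return self.__mul__(other)

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out._prev:
            def _bw(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    a.accumulate_grad(_unbroadcast(g / b.data, a.shape))
                if b.requires_grad or b._prev:
                    b.accumulate_grad(
                        _unbroadcast(-g * a.data / (b.data * b.data), b.shape)
                    )
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._prev:
            shape, nd = self.shape, self.ndim

            def _bw(g, a=self):
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    axes = tuple(ax % nd for ax in axes)
                    gg = np.expand_dims(gg, axes)
                a.accumulate_grad(np.broadcast_to(gg, shape))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._prev:
            orig = self.shape

            def _bw(g, a=self):
                a.accumulate_grad(np.asarray(g).reshape(orig))
            out._backward = _bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Iterable[Tensor]) -> Tensor:
    """Create an output node, recording parents only when a tape is needed."""
    if _GRAD_ENABLED:
        tracked = tuple(p for p in parents if p.requires_grad or p._prev)
        if tracked:
            return Tensor(data, _prev=tracked)
    return Tensor(data)
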