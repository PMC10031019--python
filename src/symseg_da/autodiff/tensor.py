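"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd style, but vectorized: every
``Tensor`` wraps a float32 ndarray, operations record a backward closure,
and :meth:`Tensor.backward` runs the tape in reverse topological order.
Only the operations needed by the translation/segmentation networks are
provided; all of them are exercised by finite-difference tests.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "astensor"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


Scalar = Union[int, float, np.floating]
TensorLike = Union["Tensor", np.ndarray, Scalar]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        arr = np.asarray(data, dtype=np.float32)
        self.data = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._prev = _prev if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if not self.requires_grad:
            raise RuntimeError("backward() called on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar backward()")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    # elementwise arithmetic
    def __add__(self, other: TensorLike) -> "Tensor":
        other = astensor(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, True, (self, other), _bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: TensorLike) -> "Tensor":
        return self + (-astensor(other))

    def __rsub__(self, other: TensorLike) -> "Tensor":
        return astensor(other) + (-self)

    def __mul__(self, other: TensorLike) -> "Tensor":
        other = astensor(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, True, (self, other), _bw)

    __rmul__ = __mul__

    def __truediv__(self, other: TensorLike) -> "Tensor":
        other = astensor(other)
        out_data = self.data / other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * out_data / other.data, other.data.shape))

        return Tensor(out_data, True, (self, other), _bw)

    def __rtruediv__(self, other: TensorLike) -> "Tensor":
        return astensor(other) / self

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, True, (self,), _bw)

    __pow__ = pow

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            self._accumulate(g * out_data)

        return Tensor(out_data, True, (self,), _bw)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            self._accumulate(g / self.data)

        return Tensor(out_data, True, (self,), _bw)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            self._accumulate(g * (1.0 - out_data * out_data))

        return Tensor(out_data, True, (self,), _bw)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, True, (self,), _bw)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0).astype(np.float32)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        return Tensor(out_data, True, (self,), _bw)

    def leaky_relu(self, alpha: float = 0.2) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, alpha * self.data).astype(np.float32)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            self._accumulate(g * np.where(mask, 1.0, alpha).astype(np.float32))

        return Tensor(out_data, True, (self,), _bw)

    def abs(self) -> "Tensor":
        out_data = np.abs(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        sign = np.sign(self.data)

        def _bw(g: np.ndarray) -> None:
            self._accumulate(g * sign)

        return Tensor(out_data, True, (self,), _bw)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp; gradient passes through only where the value is inside [lo, hi]."""
        out_data = np.clip(self.data, lo, hi)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        mask = (self.data >= lo) & (self.data <= hi)

        def _bw(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        return Tensor(out_data, True, (self,), _bw)

    # ------------------------------------------------------------------
    # reductions / shape ops
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        in_shape = self.data.shape

        def _bw(g: np.ndarray) -> None:
            gg = g
            if not keepdims and axis is not None:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                axes = tuple(a % len(in_shape) for a in axes)
                shape = tuple(1 if i in axes else s for i, s in enumerate(in_shape))
                gg = gg.reshape(shape)
            self._accumulate(np.broadcast_to(gg, in_shape).astype(np.float32))

        return Tensor(out_data, True, (self,), _bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient routed to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def _bw(g: np.ndarray) -> None:
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            self._accumulate(full)

        return Tensor(out_data, True, (self,), _bw)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        in_shape = self.data.shape

        def _bw(g: np.ndarray) -> None:
            self._accumulate(g.reshape(in_shape))

        return Tensor(out_data, True, (self,), _bw)


def astensor(x: TensorLike) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g: np.ndarray) -> None:
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor(out_data, True, tuple(tensors), _bw)
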