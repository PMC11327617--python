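"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  The op set is exactly what the attention /
survival models in this package need (broadcasted arithmetic, batched matmul,
reductions, exp/log/tanh, gather/scatter indexing, concatenation) — it is not
a general framework and does not try to be one.

All shapes follow numpy broadcasting; gradients of broadcasted operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "as_tensor"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- graph ops
    def _make(self, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_sum_to_shape(g, a.data.shape))
            if b.requires_grad:
                b._accum(_sum_to_shape(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_sum_to_shape(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_sum_to_shape(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other._reciprocal()

    def __rtruediv__(self, other):
        return as_tensor(other) * self._reciprocal()

    def _reciprocal(self):
        a = self
        out_data = 1.0 / a.data

        def backward(g):
            if a.requires_grad:
                a._accum(_sum_to_shape(-g * out_data * out_data, a.data.shape))

        return self._make(out_data, (a,), backward)

    def __pow__(self, p: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return self._make(a.data**p, (a,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_sum_to_shape(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_sum_to_shape(gb, b.data.shape))

        return self._make(a.data @ b.data, (a, b), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        return self**0.5

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data * out_data))

        return self._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        c = np.sqrt(2.0 / np.pi)
        x = self
        return 0.5 * x * (1.0 + (c * (x + 0.044715 * x * x * x)).tanh())

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * sign)

        return self._make(np.abs(a.data), (a,), backward)

    def clamp_min(self, lo: float):
        a = self
        mask = a.data > lo

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return self._make(np.maximum(a.data, lo), (a,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------------- shape plumbing
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(np.transpose(g, inv))

        return self._make(np.transpose(a.data, axes), (a,), backward)

    def swapaxes(self, i: int, j: int):
        axes = list(range(self.data.ndim))
        axes[i], axes[j] = axes[j], axes[i]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                acc = np.zeros_like(a.data, dtype=np.result_type(a.data, g))
                np.add.at(acc, idx, g)
                a._accum(acc)

        return self._make(a.data[idx], (a,), backward)

    @staticmethod
    def concatenate(tensors: Iterable["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [as_tensor(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        data = np.concatenate([t.data for t in tensors], axis=axis)
        req = is_grad_enabled() and any(t.requires_grad for t in tensors)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(tensors)
            out._backward = backward
        return out

    # ------------------------------------------------------------- composites
    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable softmax (max-subtracted) along ``axis``."""
        shift = np.max(self.data, axis=axis, keepdims=True)
        e = (self - Tensor(shift)).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis: int = -1, keepdims: bool = False) -> "Tensor":
        shift = np.max(self.data, axis=axis, keepdims=True)
        out = (self - Tensor(shift)).exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)
        if not keepdims:
            out = out.reshape(tuple(np.delete(out.data.shape, axis)))
        return out

    # --------------------------------------------------------------- backward
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar output")
            grad = np.ones_like(self.data, dtype=float)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free interior gradients and graph refs as we go
                if node is not self:
                    node._backward = None
                    node._parents = ()
                    node.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
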