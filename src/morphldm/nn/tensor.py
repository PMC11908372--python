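"""Reverse-mode autodiff on numpy arrays.

A small tape-based engine sized for the needs of this package: dense 3D
convolutional networks, a differentiable trilinear grid-sampler, batched
matrix products for attention, and the usual pointwise/reduction ops.
Gradients are accumulated in ``Tensor.grad`` by :meth:`Tensor.backward`,
which topologically sorts the tape and runs each node's backward closure.

Arrays keep whatever float dtype they were created with; intermediate
gradients match the forward dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar Tensor")
            grad = np.ones_like(self.data)
        # topo sort
        topo, seen = [], set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray):
        if not t.requires_grad:
            return
        g = _unbroadcast(np.asarray(g), t.data.shape)
        if t.grad is None:
            t.grad = g.astype(t.data.dtype, copy=True)
        else:
            t.grad += g

    # -------------------------------------------------------------- pointwise
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad

        def bw(g):
            Tensor._accum(self, g)
            Tensor._accum(other, g)

        return Tensor(out_data, req, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            Tensor._accum(self, -g)

        return Tensor(-self.data, self.requires_grad, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad

        def bw(g):
            Tensor._accum(self, g * other.data)
            Tensor._accum(other, g * self.data)

        return Tensor(out_data, req, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data
        req = self.requires_grad or other.requires_grad

        def bw(g):
            Tensor._accum(self, g / other.data)
            Tensor._accum(other, -g * self.data / (other.data ** 2))

        return Tensor(out_data, req, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            Tensor._accum(self, g * p * self.data ** (p - 1))

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            Tensor._accum(self, g * out_data)

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def log(self):
        def bw(g):
            Tensor._accum(self, g / self.data)

        return Tensor(np.log(self.data), self.requires_grad, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            Tensor._accum(self, g * 0.5 / out_data)

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def abs(self):
        def bw(g):
            Tensor._accum(self, g * np.sign(self.data))

        return Tensor(np.abs(self.data), self.requires_grad, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            Tensor._accum(self, g * mask)

        return Tensor(self.data * mask, self.requires_grad, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)

        def bw(g):
            Tensor._accum(self, g * factor)

        return Tensor(self.data * factor, self.requires_grad, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            Tensor._accum(self, g * out_data * (1.0 - out_data))

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            Tensor._accum(self, g * (1.0 - out_data ** 2))

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            Tensor._accum(self, out_data * (g - dot))

        return Tensor(out_data, self.requires_grad, (self,), bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is None:
                Tensor._accum(self, np.broadcast_to(g, shape))
            else:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                if not keepdims:
                    g = np.expand_dims(g, tuple(a % len(shape) for a in axes))
                Tensor._accum(self, np.broadcast_to(g, shape))

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in ((axis,) if np.isscalar(axis) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bw(g):
            Tensor._accum(self, g.reshape(orig))

        return Tensor(self.data.reshape(shape), self.requires_grad, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            Tensor._accum(self, g.transpose(inv))

        return Tensor(self.data.transpose(axes), self.requires_grad, (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            Tensor._accum(self, g.swapaxes(a, b))

        return Tensor(self.data.swapaxes(a, b), self.requires_grad, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def bw(g):
            full = np.zeros(shape, dtype=g.dtype)
            np.add.at(full, idx, g)
            Tensor._accum(self, full)

        return Tensor(out_data, self.requires_grad, (self,), bw)

    # ------------------------------------------------------------------ blas
    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad

        def bw(g):
            Tensor._accum(self, g @ np.swapaxes(other.data, -1, -2))
            Tensor._accum(other, np.swapaxes(self.data, -1, -2) @ g)

        return Tensor(out_data, req, (self, other), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            Tensor._accum(t, g[tuple(sl)])

    return Tensor(out_data, req, tuple(tensors), bw)
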