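"""Array-valued reverse-mode automatic differentiation.

A deliberately small tape-based engine: each :class:`Tensor` wraps a NumPy
array and remembers how to push its cotangent back to its parents.  The op
set is exactly what an encoder--decoder segmentation network needs — elementwise
arithmetic with broadcasting, reductions (mean / max with axis), sigmoid /
ReLU / log, channel concatenation and slicing, matrix products — plus the
convolution and resampling primitives defined in :mod:`dmffnet.nn.functional`.

Gradients accumulate into ``Tensor.grad`` (a plain ndarray) during
:meth:`Tensor.backward`, which walks the graph in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=[p for p in parents if p.requires_grad],
                      backward=backward if req else None)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor.make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor.make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor.make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.data.shape))

        return Tensor.make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor.make(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor.make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * s * (1.0 - s))

        return Tensor.make(s, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor.make(np.log(self.data), (self,), backward)

    def sqrt(self):
        r = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / r)

        return Tensor.make(r, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accum(g * mask)

        return Tensor.make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g2, self.data.shape).copy())

        return Tensor.make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int | tuple, keepdims: bool = True):
        out_data = self.data.max(axis=axis, keepdims=True)
        # ties share the cotangent equally, keeping the op symmetric
        mask = (self.data == out_data).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)

        def backward(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * g2)

        return Tensor.make(out_data if keepdims else out_data.squeeze(axis), (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor.make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor.make(self.data.transpose(axes), (self,), backward)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along ``axis`` (used for channel-group splitting)."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor.make(self.data[idx], (self,), backward)

    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        return Tensor.make(out_data, (self, other), backward)

    __matmul__ = matmul

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- backward pass --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if id(p) not in seen:
                    stack.append((p, False))

        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``; gradient splits back by segment."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])

    return Tensor.make(out_data, tuple(tensors), backward)
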