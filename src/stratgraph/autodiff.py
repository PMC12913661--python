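"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains its graph/attention encoder, risk head and intervention
decoder with gradient descent; every differentiable computation is expressed
through the :class:`Tensor` type defined here.  The engine is deliberately
small: dense float64 arrays, dynamic tape, topological-order backward pass.
Correctness is validated against central finite differences in the test
suite (relative error < 1e-4 on a small model, and much tighter on
individual ops).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "stack", "softmax", "log_softmax", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were 1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode pass.  The tape is single-use: intermediate nodes are
        released afterwards (breaking reference cycles), so only leaf
        gradients survive."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                stack.pop()
                if node.requires_grad:
                    topo.append(node)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        for node in topo:
            if node._prev:
                node._backward = None
                node._prev = ()
                node.grad = None

    def release(self) -> None:
        """Break the reference cycles of an un-backpropagated graph."""
        stack, seen = [self], set()
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.extend(node._prev)
            node._backward = None
            node._prev = ()

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad)
            if other.requires_grad:
                other._accum(out.grad)

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda: self.requires_grad and self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * other.data)
            if other.requires_grad:
                other._accum(out.grad * self.data)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / other.data)
            if other.requires_grad:
                other._accum(-out.grad * self.data / other.data**2)

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = tensor(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def _bw():
            if self.requires_grad:
                g = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accum(g)
            if other.requires_grad:
                g = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._accum(g)

        out._backward = _bw
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda: self.requires_grad and self._accum(out.grad * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda: self.requires_grad and self._accum(out.grad / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda: self.requires_grad and self._accum(
            out.grad * (1.0 - out.data**2)
        )
        return out

    def sigmoid(self):
        with np.errstate(over="ignore"):  # saturates cleanly at 0/1
            s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda: self.requires_grad and self._accum(
            out.grad * out.data * (1.0 - out.data)
        )
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda: self.requires_grad and self._accum(
            out.grad * (self.data > 0)
        )
        return out

    def sqrt(self):
        return self**0.5

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---------------------------------------------------------------- shapes
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda: self.requires_grad and self._accum(
            out.grad.reshape(self.data.shape)
        )
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))
        out._backward = lambda: self.requires_grad and self._accum(
            np.swapaxes(out.grad, a, b)
        )
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw():
            if not self.requires_grad:
                return
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out._backward = _bw
        return out

    # ----------------------------------------------------------------- misc
    def graph_prop(self, P: np.ndarray):
        """Propagate node states over a fixed (non-differentiable) operator.

        Computes ``einsum('ij,j...->i...', P, self)`` — the first axis indexes
        graph nodes, trailing axes (time, features) are carried along.
        """
        P = np.asarray(P, dtype=np.float64)
        out = Tensor(np.tensordot(P, self.data, axes=(1, 0)), _prev=(self,))
        out._backward = lambda: self.requires_grad and self._accum(
            np.tensordot(P.T, out.grad, axes=(1, 0))
        )
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def _bw():
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        pieces = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(g)

    out._backward = _bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = tensor(t)
        shape = list(t.data.shape)
        shape.insert(axis if axis >= 0 else t.data.ndim + 1 + axis, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax; `mask` (bool, True = keep) zeroes positions."""
    x = tensor(x)
    if mask is not None:
        penalty = np.where(mask, 0.0, -1e30)
        x = x + Tensor(penalty)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, gradient-safe
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    x = tensor(x)
    if mask is not None:
        x = x + Tensor(np.where(mask, 0.0, -1e30))
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return tensor(x)
    keep = rng.random(tensor(x).shape) >= rate
    return tensor(x) * Tensor(keep / (1.0 - rate))
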