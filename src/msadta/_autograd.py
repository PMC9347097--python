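"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape: each operation returns a :class:`Tensor` holding the result,
its parents, and a closure that routes the upstream gradient to the parents
(with broadcast reduction).  ``Tensor.backward()`` runs the tape in reverse
topological order.  Float64 throughout, which keeps finite-difference
gradient checks tight.  Only the operations the affinity model needs are
provided.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self.grad: np.ndarray | None = None

    # ---- graph -----------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
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
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- helpers ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @staticmethod
    def wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor.wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor.wrap(other))

    def __rsub__(self, other):
        return Tensor.wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor.wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (
            self._accum(g * other.data),
            other._accum(g * self.data),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        out._backward = lambda g: (
            self._accum(g / other.data),
            other._accum(-g * self.data / other.data**2),
        )
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = Tensor.wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = backward
        return out

    # ---- elementwise -----------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    # ---- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose_last2(self):
        out = Tensor(np.swapaxes(self.data, -1, -2), parents=(self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, -1, -2))
        return out

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            data = np.squeeze(data, axis=axis)
        out = Tensor(data, parents=(self,))

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(full)

        out._backward = backward
        return out

    # ---- composites ------------------------------------------------------
    def softmax(self, axis: int = -1):
        shift = self.data.max(axis=axis, keepdims=True)  # constant: no grad
        e = (self - Tensor(shift)).exp()
        return e / e.sum(axis=axis, keepdims=True)


def take_rows(table: Tensor, ids: np.ndarray) -> Tensor:
    """Embedding lookup ``table[ids]`` with scatter-add gradient."""
    ids = np.asarray(ids)
    out = Tensor(table.data[ids], parents=(table,))

    def backward(g):
        if not table.requires_grad:
            return
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, ids, g)

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    sizes = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, sizes, axis=axis)):
            t._accum(piece)

    out._backward = backward
    return out


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
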