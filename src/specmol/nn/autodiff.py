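"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations producing it;
``backward()`` walks the graph in reverse topological order accumulating
gradients. The operation set is exactly what the encoders need: broadcasting
arithmetic, (batched) matmul, relu, exp, log, scalar powers, axis
reductions, reshape/swapaxes, and matmul with a constant (optionally
scipy-sparse) left operand for graph convolutions and pooling.

Gradients of broadcast operations are reduced back to the operand shape with
:func:`_unbroadcast`. Correctness is established against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            a._accum(-g)

        return self._make(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self

        def back(g):
            a._accum(g * p * a.data ** (p - 1))

        return self._make(a.data ** p, (a,), back)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2) if b.data.ndim > 1 else np.outer(g, b.data)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g if a.data.ndim > 1 else np.outer(a.data, g)
                b._accum(_unbroadcast(gb, b.shape))

        return self._make(a.data @ b.data, (a, b), back)

    # -- elementwise nonlinearities ---------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def back(g):
            a._accum(g * mask)

        return self._make(a.data * mask, (a,), back)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def back(g):
            a._accum(g * out_data)

        return self._make(out_data, (a,), back)

    def log(self):
        a = self

        def back(g):
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), back)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def back(g):
            a._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (a,), back)

    # -- reductions / shape -----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def back(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        old = a.shape

        def back(g):
            a._accum(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), back)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def back(g):
            a._accum(np.swapaxes(g, ax1, ax2))

        return self._make(np.swapaxes(a.data, ax1, ax2), (a,), back)

    def diag(self):
        """Diagonal of a square matrix (used for positive-pair scores)."""
        a = self
        n = a.shape[0]

        def back(g):
            gg = np.zeros_like(a.data)
            np.fill_diagonal(gg, g)
            a._accum(gg)

        return self._make(np.diagonal(a.data).copy(), (a,), back)

    def detach(self) -> np.ndarray:
        return self.data.copy()


def const_matmul(mat, t: Tensor) -> Tensor:
    """``mat @ t`` where ``mat`` is a constant ndarray or scipy sparse matrix.

    Used for normalized-adjacency propagation and mean pooling, whose
    structure matrices carry no gradient.
    """

    def back(g):
        t._accum(mat.T @ g)

    out_data = mat @ t.data
    out = Tensor(out_data, requires_grad=t.requires_grad)
    if out.requires_grad:
        out._parents = (t,)
        out._backward = back
    return out


def softmax_last(t: Tensor) -> Tensor:
    """Numerically stable softmax over the last axis (detached max shift)."""
    shift = t.data.max(axis=-1, keepdims=True)
    e = (t - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def logsumexp_last(t: Tensor) -> Tensor:
    shift = t.data.max(axis=-1, keepdims=True)
    return (t - shift).exp().sum(axis=-1).log() + Tensor(shift[..., 0])
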