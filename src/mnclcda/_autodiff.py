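"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine covering exactly the operations the model needs:
dense matrix products, elementwise arithmetic with broadcasting, rectifier
and sigmoid nonlinearities, reductions, concatenation, row slicing and a
fused Gaussian-kernel op.  Gradients are accumulated by a topological sweep
over the recorded graph.  Correctness is pinned against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over broadcast dimensions so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value: np.ndarray | float,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ) -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph mechanics -------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar) node."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=float)
        else:
            self.grad = self.grad + grad

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def T(self) -> "Tensor":
        return transpose(self)

    def item(self) -> float:
        return float(self.value)

    def __add__(self, other):
        return add(self, as_tensor(other))

    def __radd__(self, other):
        return add(as_tensor(other), self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    def __rmul__(self, other):
        return mul(as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __rmatmul__(self, other):
        return matmul(as_tensor(other), self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(value: np.ndarray) -> Tensor:
    return Tensor(np.array(value, dtype=float), requires_grad=True)


# -- primitive operations ------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value + b.value, (a, b))

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad, b.value.shape))

    out._backward = backward
    return out


def neg(a: Tensor) -> Tensor:
    out = Tensor(-a.value, (a,))
    out._backward = lambda grad: a.requires_grad and a._accumulate(-grad)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value * b.value, (a, b))

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad * b.value, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad * a.value, b.value.shape))

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value @ b.value, (a, b))

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad @ b.value.T)
        if b.requires_grad:
            b._accumulate(a.value.T @ grad)

    out._backward = backward
    return out


def transpose(a: Tensor) -> Tensor:
    out = Tensor(a.value.T, (a,))
    out._backward = lambda grad: a.requires_grad and a._accumulate(grad.T)
    return out


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = a.value.shape
    out = Tensor(a.value.reshape(shape), (a,))
    out._backward = lambda grad: a.requires_grad and a._accumulate(grad.reshape(orig))
    return out


def power(a: Tensor, exponent: float) -> Tensor:
    out = Tensor(a.value**exponent, (a,))

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * exponent * a.value ** (exponent - 1.0))

    out._backward = backward
    return out


def exp(a: Tensor) -> Tensor:
    val = np.exp(a.value)
    out = Tensor(val, (a,))
    out._backward = lambda grad: a.requires_grad and a._accumulate(grad * val)
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.value), (a,))
    out._backward = lambda grad: a.requires_grad and a._accumulate(grad / a.value)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.value > 0
    out = Tensor(a.value * mask, (a,))
    out._backward = lambda grad: a.requires_grad and a._accumulate(grad * mask)
    return out


def sigmoid(a: Tensor) -> Tensor:
    val = expit(a.value)
    out = Tensor(val, (a,))
    out._backward = lambda grad: a.requires_grad and a._accumulate(grad * val * (1.0 - val))
    return out


def softplus(a: Tensor) -> Tensor:
    """``log(1 + exp(x))`` evaluated overflow-free; gradient is sigmoid(x)."""
    x = a.value
    val = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(val, (a,))
    sig = expit(x)
    out._backward = lambda grad: a.requires_grad and a._accumulate(grad * sig)
    return out


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    mask = (a.value > lo) & (a.value < hi)
    out = Tensor(np.clip(a.value, lo, hi), (a,))
    out._backward = lambda grad: a.requires_grad and a._accumulate(grad * mask)
    return out


def tsum(a: Tensor, axis: int | None = None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.value.sum(axis=axis, keepdims=keepdims), (a,))

    def backward(grad):
        if not a.requires_grad:
            return
        g = grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.value.shape).copy())

    out._backward = backward
    return out


def tmean(a: Tensor, axis: int | None = None, keepdims: bool = False) -> Tensor:
    count = a.value.size if axis is None else a.value.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / count))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * grad.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(grad[tuple(idx)])

    out._backward = backward
    return out


def rows(a: Tensor, start: int, stop: int) -> Tensor:
    out = Tensor(a.value[start:stop], (a,))

    def backward(grad):
        if a.requires_grad:
            full = np.zeros_like(a.value)
            full[start:stop] = grad
            a._accumulate(full)

    out._backward = backward
    return out


def gaussian_kernel(E: Tensor, gamma: float) -> Tensor:
    """Fused ``K[i,j] = exp(-gamma * ||E_i - E_j||^2)`` with analytic gradient."""
    V = E.value
    sq = (V**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * V @ V.T, 0.0)
    K = np.exp(-gamma * d2)
    out = Tensor(K, (E,))

    def backward(grad):
        if not E.requires_grad:
            return
        G = grad * K
        S = G + G.T
        E._accumulate(-2.0 * gamma * (S.sum(axis=1)[:, None] * V - S @ V))

    out._backward = backward
    return out
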