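"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is deliberately a small tape: just the operations the feed-forward
potential needs (affine layers, smooth activations, batched matrix
products, slicing, quadratic losses).  The crucial design point is that
the *input-Jacobian of the energy heads is itself built as an explicit
expression in the graph* (products of weight matrices and activation
derivatives), so a quadratic loss on predicted forces is differentiated
with respect to the weights by a single ordinary backward pass — no
nested tapes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward op."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("value", "grad", "_parents", "requires_grad")

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        #: list of (parent Tensor, vjp function grad -> parent grad)
        self._parents = parents
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)

    @property
    def shape(self):
        return self.value.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the graph."""
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        self.grad = np.ones(())
        for node in reversed(order):
            for parent, vjp in node._parents:
                if not parent.requires_grad:
                    continue
                g = vjp(node.grad)
                parent.grad = g if parent.grad is None else parent.grad + g


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.value + b.value, parents=(
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(g, b.shape)),
    ))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.value - b.value, parents=(
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(-g, b.shape)),
    ))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.value * b.value, parents=(
        (a, lambda g: _unbroadcast(g * b.value, a.shape)),
        (b, lambda g: _unbroadcast(g * a.value, b.shape)),
    ))


def scale(a: Tensor, s: float) -> Tensor:
    return Tensor(a.value * s, parents=((a, lambda g: g * s),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """np.matmul semantics, including batched (B, m, k) @ (k, n) etc."""
    def da(g):
        return _unbroadcast(np.matmul(g, np.swapaxes(b.value, -1, -2)), a.shape)

    def db(g):
        return _unbroadcast(np.matmul(np.swapaxes(a.value, -1, -2), g), b.shape)

    return Tensor(np.matmul(a.value, b.value), parents=((a, da), (b, db)))


def softplus_shifted(a: Tensor) -> Tensor:
    """Shifted softplus ln(0.5 e^x + 0.5) = softplus(x) - ln 2 (smooth, ssp(0)=0)."""
    v = np.logaddexp(0.0, a.value) - np.log(2.0)
    sig = expit(a.value)
    return Tensor(v, parents=((a, lambda g: g * sig),))


def sigmoid(a: Tensor) -> Tensor:
    s = expit(a.value)
    return Tensor(s, parents=((a, lambda g: g * s * (1.0 - s)),))


def transpose2d(a: Tensor) -> Tensor:
    return Tensor(a.value.T, parents=((a, lambda g: g.T),))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape
    return Tensor(a.value.reshape(shape),
                  parents=((a, lambda g: g.reshape(old)),))


def take_last(a: Tensor, start: int, stop: int) -> Tensor:
    """Slice [start:stop] along the last axis."""
    def back(g):
        out = np.zeros(a.shape)
        out[..., start:stop] = g
        return out

    return Tensor(a.value[..., start:stop], parents=((a, back),))


def expand_dim(a: Tensor, axis: int) -> Tensor:
    return Tensor(np.expand_dims(a.value, axis),
                  parents=((a, lambda g: np.squeeze(g, axis=axis)),))


def sum_all(a: Tensor) -> Tensor:
    return Tensor(a.value.sum(), parents=((a, lambda g: g * np.ones(a.shape)),))


def sum_squares(a: Tensor) -> Tensor:
    return Tensor((a.value ** 2).sum(), parents=((a, lambda g: g * 2.0 * a.value),))
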