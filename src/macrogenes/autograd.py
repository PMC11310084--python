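"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The integration model is small (a handful of dense layers, layer
normalization, a ZINB likelihood and a few cosine-similarity losses), so
rather than depending on a deep-learning framework the package carries a
compact tape-based autodiff engine.  Every primitive registers a backward
closure; gradients are accumulated by a reverse topological sweep.  All
primitives are gradient-checked against central finite differences in the
test suite.

Broadcasting follows NumPy semantics: backward passes sum gradients over
broadcast axes (``_unbroadcast``).
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "concat", "logaddexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        return Tensor._make(self.data @ other.data, (self, other), backward)

    def transpose(self) -> "Tensor":
        return Tensor._make(self.data.T, (self,), lambda g: (g.T,))

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g_ = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def log1p(self):
        return Tensor._make(np.log1p(self.data), (self,), lambda g: (g / (1.0 + self.data),))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._make(np.where(mask, self.data, 0.0), (self,), backward)

    def sigmoid(self):
        out_data = _sp.expit(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def softplus(self):
        # log(1 + e^x), stable for large |x|
        out_data = np.logaddexp(0.0, self.data)
        sig = _sp.expit(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * sig,))

    def lgamma(self):
        def backward(g):
            return (g * _sp.digamma(self.data),)

        return Tensor._make(_sp.gammaln(self.data), (self,), backward)

    # -- backward ------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of `self` into every reachable leaf."""
        if not self.requires_grad:
            raise RuntimeError("called backward on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for parent, pg in zip(node._parents, parent_grads):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg
        # leaves with no _backward already stored; also store for parametrised
        # intermediates the user kept a reference to
        for node in order:
            if id(node) in grads:
                g = grads[id(node)]
                node.grad = g if node.grad is None else node.grad + g


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis` with gradient routing."""
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.array_split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise log(e^a + e^b), stable, with sigmoid-weighted gradients."""
    a, b = _as_tensor(a), _as_tensor(b)
    wa = _sp.expit(a.data - b.data)

    def backward(g):
        return (
            _unbroadcast(g * wa, a.shape),
            _unbroadcast(g * (1.0 - wa), b.shape),
        )

    return Tensor._make(np.logaddexp(a.data, b.data), (a, b), backward)
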