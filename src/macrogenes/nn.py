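"""Small neural-network building blocks on top of :mod:`macrogenes.autograd`.

Contains exactly what the integration model needs: dense layers, layer
normalization with learnable affine parameters, inverted dropout, a
numerically stable row softmax, row-wise cosine similarity, and Adam.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Parameter",
    "linear",
    "layer_norm",
    "dropout",
    "softmax_rows",
    "cosine_rows",
    "inverse_softplus",
    "Adam",
    "he_init",
]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """He-normal initialization, appropriate for ReLU layers."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    return x @ weight + bias


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine.

    Uses the biased (1/n) variance, matching the usual definition.
    """
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gamma + beta


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return x * Tensor(mask)


def softmax_rows(logits: Tensor) -> Tensor:
    """Softmax over the last axis; the row max is detached (shift invariance)."""
    shifted = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)


def cosine_rows(a: Tensor, b: Tensor, zero_norm_value: float = 0.0) -> Tensor:
    """Row-wise cosine similarity between two equally shaped 2-D tensors.

    Rows whose norm is exactly zero in either operand get `zero_norm_value`
    (gradient zero there), so dead units never produce NaNs.
    """
    num = (a * b).sum(axis=-1)
    na = (a**2).sum(axis=-1)
    nb = (b**2).sum(axis=-1)
    dead = (na.data == 0.0) | (nb.data == 0.0)
    # keep the denominator bounded away from 0 on dead rows; they are masked out
    denom = ((na + float(np.finfo(float).tiny)) * (nb + float(np.finfo(float).tiny))).sqrt()
    safe = num / denom * Tensor((~dead).astype(float))
    if zero_norm_value != 0.0 and dead.any():
        safe = safe + Tensor(dead.astype(float) * zero_norm_value)
    return safe


def inverse_softplus(y: np.ndarray) -> np.ndarray:
    """x such that log(1 + e^x) = y, stable for small and large y."""
    y = np.asarray(y, dtype=np.float64)
    # log(e^y - 1) = y + log(1 - e^-y)
    return y + np.log(-np.expm1(-y))


class Adam:
    """Adam with bias correction; operates in place on parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
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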