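"""Optimizers and the softmax cross-entropy loss."""

from __future__ import annotations

from typing import Optional

import numpy as np

from airsig.nn.layers import Parameter


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weight: Optional[np.ndarray] = None
) -> tuple[float, np.ndarray]:
    """Weighted mean cross-entropy; returns (loss, dL/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    if sample_weight is None:
        sample_weight = np.ones(n)
    total = sample_weight.sum()
    eps = 1e-12
    loss = float(-(sample_weight * np.log(p[np.arange(n), y] + eps)).sum() / total)
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (sample_weight / total)[:, None]
    return loss, grad


class Optimizer:
    def __init__(self, params: list[Parameter]):
        self.params = list(params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float, momentum: float = 0.0):
        super().__init__(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


class Adam(Optimizer):
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Adadelta(Optimizer):
    """Classic Adadelta; `lr` scales the adaptive update (1.0 in the original)."""

    def __init__(self, params, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6):
        super().__init__(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self._eg = [np.zeros_like(p.value) for p in self.params]
        self._ed = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, eg, ed in zip(self.params, self._eg, self._ed):
            eg *= self.rho
            eg += (1.0 - self.rho) * p.grad**2
            delta = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * p.grad
            ed *= self.rho
            ed += (1.0 - self.rho) * delta**2
            p.value += self.lr * delta
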