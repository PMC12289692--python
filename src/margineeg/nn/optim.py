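"""Optimizers and classification losses for the autograd stack."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["SGD", "AdamW", "cross_entropy"]


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class AdamW(SGD):
    """Adam with decoupled weight decay (the decay multiplies the weight
    directly rather than entering the gradient moments)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        super().__init__(params, lr=lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer class labels under softmax logits."""
    labels = np.asarray(labels, dtype=int)
    n = logits.shape[0]
    logp = logits - _logsumexp(logits)
    picked = logp[np.arange(n), labels]
    return -picked.mean()


def _logsumexp(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    return ((logits - shift).exp().sum(axis=-1, keepdims=True)).log() + shift
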