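"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "cosine_lr"]


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(epoch: int, total_epochs: int, lr0: float, lr_min: float) -> float:
    """Cosine annealing from ``lr0`` (epoch 0) to ``lr_min`` (last epoch)."""
    if not 0 <= epoch < total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    if total_epochs == 1:
        return lr0
    frac = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * frac))
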