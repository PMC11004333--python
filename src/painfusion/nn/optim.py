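"""Optimisation: AdamW with decoupled weight decay and a warmup/cosine schedule."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW", "cosine_warmup_lr"]


class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter convention)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.1):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


def cosine_warmup_lr(epoch: int, base_lr: float, warmup_epochs: int,
                     total_epochs: int, min_lr: float = 0.0) -> float:
    """Linear warmup followed by cosine decay to ``min_lr``."""
    if warmup_epochs > 0 and epoch < warmup_epochs:
        return base_lr * (epoch + 1) / warmup_epochs
    span = max(total_epochs - warmup_epochs, 1)
    progress = min((epoch - warmup_epochs) / span, 1.0)
    return min_lr + 0.5 * (base_lr - min_lr) * (1 + math.cos(math.pi * progress))
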