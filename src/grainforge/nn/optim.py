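"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Adam", "cosine_lr"]


class Adam:
    """Adam with optional decoupled-style L2 weight decay (added to the grad)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data.reshape(p.data.shape).astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(initial: float, final: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from ``initial`` down to ``final`` over ``total_epochs``."""
    if total_epochs <= 1:
        return initial
    frac = min(max(epoch / (total_epochs - 1), 0.0), 1.0)
    return final + 0.5 * (initial - final) * (1 + math.cos(math.pi * frac))
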