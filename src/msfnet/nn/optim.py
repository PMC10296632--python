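"""Optimisation: Adam with decoupled-from-nothing (classic L2) weight decay,
plus the one-step learning-rate drop schedule used for training."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "step_lr"]


class Adam:
    """Adam (Kingma & Ba) over a list of parameters.

    ``weight_decay`` is classic L2 regularisation folded into the gradient,
    matching the common framework default.
    """

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
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
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


def step_lr(base_lr: float, epoch: int, drop_epoch: int, factor: float) -> float:
    """Learning rate for 1-indexed ``epoch``: ``base_lr`` up to and including
    ``drop_epoch``, multiplied by ``factor`` afterwards (a single late drop)."""
    return base_lr * factor if epoch > drop_epoch else base_lr
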