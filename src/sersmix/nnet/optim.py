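"""AdamW with decoupled weight decay and a cosine-annealing LR schedule."""

from __future__ import annotations

import math

import numpy as np

from .layers import Param


def cosine_annealing_lr(step: int, total_steps: int, lr: float, lr_min: float) -> float:
    """Learning rate at ``step`` (0-based); reaches ``lr_min`` exactly at
    ``step == total_steps``."""
    t = min(max(step, 0), total_steps) / total_steps
    return lr_min + 0.5 * (lr - lr_min) * (1.0 + math.cos(math.pi * t))


class AdamW:
    """Adam with decoupled weight decay (no decay on biases/BN by convention
    of the caller; this class decays every param it is given)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            mhat = m / b1t
            vhat = v / b2t
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                  + self.weight_decay * p.value)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
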