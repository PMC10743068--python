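"""Adam optimizer with L2 weight decay and a step-decay learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .core import Module


class Adam:
    def __init__(self, model: Module, lr=1e-3, weight_decay=0.0,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for p in model.parameters() if p.trainable]
        self.base_lr = lr
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def set_lr(self, lr: float):
        self.lr = lr

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def step_decay_lr(base_lr: float, epoch: int, factor: float, every_n: int) -> float:
    """Learning rate after `epoch` completed epochs under a step-decay schedule."""
    return base_lr * factor ** (epoch // every_n)
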