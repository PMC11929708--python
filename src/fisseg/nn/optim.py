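"""Adam optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
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
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(epoch: int, total_epochs: int, lr_max: float,
              floor_factor: float = 0.05) -> float:
    """Cosine annealing from lr_max (epoch 0) to floor_factor*lr_max (last).

    With T = total_epochs - 1:  lr(e) = lr_min + (lr_max-lr_min)/2 * (1+cos(pi e/T)).
    """
    lr_min = floor_factor * lr_max
    if total_epochs <= 1:
        return lr_max
    t = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + np.cos(np.pi * t))


class CosineAnnealing:
    """Attachable schedule: call .step(epoch) to update optimizer.lr."""

    def __init__(self, optimizer: Adam, total_epochs: int,
                 floor_factor: float = 0.05):
        self.optimizer = optimizer
        self.total_epochs = total_epochs
        self.floor_factor = floor_factor
        self.lr_max = optimizer.lr

    def step(self, epoch: int):
        self.optimizer.lr = cosine_lr(
            epoch, self.total_epochs, self.lr_max, self.floor_factor)
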