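"""Optimisers for autograd parameters."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam"]


class Adam:
    """Adam with optional cosine learning-rate decay.

    `total_steps` enables cosine decay from `lr` to `lr * min_lr_frac`;
    left at None the learning rate is constant.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 total_steps: int | None = None, min_lr_frac: float = 0.1):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.total_steps = total_steps
        self.min_lr_frac = min_lr_frac
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        if self.total_steps is None:
            return self.lr
        frac = min(self.t / max(self.total_steps, 1), 1.0)
        lo = self.lr * self.min_lr_frac
        return lo + 0.5 * (self.lr - lo) * (1.0 + np.cos(np.pi * frac))

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        lr = self.current_lr()
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)
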