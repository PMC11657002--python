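"""Optimisers and learning-rate schedules used by the training stages."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with L2 weight decay folded into the gradient.

    Defaults mirror the training recipe used throughout the pipeline:
    betas (0.9, 0.999), eps 1e-8, weight decay 0.1.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.1,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class StepHalving:
    """Halve the learning rate every ``every`` epochs."""

    def __init__(self, optimizer: Adam, every: int = 25):
        self.optimizer = optimizer
        self.every = int(every)
        self._base_lr = optimizer.lr

    def at_epoch(self, epoch: int) -> None:
        """Set the LR for 0-based ``epoch`` (halved after each ``every`` block)."""
        self.optimizer.lr = self._base_lr * 0.5 ** (epoch // self.every)


class ReduceOnPlateau:
    """Divide the LR by ``factor`` when a monitored loss stops improving.

    Improvement means dropping below the best seen value by at least ``tol``;
    at most ``max_decays`` reductions are applied, then the LR holds.
    """

    def __init__(self, optimizer: Adam, factor: float = 10.0, tol: float = 1e-4,
                 max_decays: int = 3):
        self.optimizer = optimizer
        self.factor = factor
        self.tol = tol
        self.max_decays = max_decays
        self.best = np.inf
        self.decays = 0

    def update(self, value: float) -> bool:
        """Feed the latest monitored value; returns True if the LR was decayed."""
        if value < self.best - self.tol:
            self.best = value
            return False
        if self.decays < self.max_decays:
            self.optimizer.lr /= self.factor
            self.decays += 1
            return True
        return False
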