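"""Adam optimizer and plateau learning-rate scheduling."""

from __future__ import annotations

import numpy as np


class Adam:
    """Standard Adam; state is keyed by parameter name."""

    def __init__(self, param_names, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: None for k in param_names}
        self.v = {k: None for k in param_names}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for k, g in grads.items():
            if g is None:
                continue
            if self.m[k] is None:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` when the monitored loss stalls."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 10,
                 min_lr: float = 1e-6):
        if not 0 < factor < 1:
            raise ValueError("factor must lie in (0, 1)")
        self.opt = optimizer
        self.factor, self.patience, self.min_lr = factor, patience, min_lr
        self.best = np.inf
        self.stale = 0

    def step(self, monitored: float) -> None:
        if monitored < self.best - 1e-12:
            self.best = monitored
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.stale = 0
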