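"""Adam optimiser and the two Keras-style training callbacks the schedule uses."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-7):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimiser learning rate when the monitored
    quantity stops improving by more than ``min_delta`` for ``patience`` epochs.
    Monitors a maximised quantity (validation accuracy)."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_delta: float = 1e-4, min_lr: float = 0.0):
        self.opt = optimizer
        self.factor, self.patience, self.min_delta, self.min_lr = factor, patience, min_delta, min_lr
        self.best = -np.inf
        self.wait = 0

    def step(self, metric: float):
        if metric > self.best + self.min_delta:
            self.best = metric
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.wait = 0


class EarlyStopping:
    """Stop when the monitored (maximised) metric has not improved by
    ``min_delta`` for ``patience`` epochs; optionally restore best weights."""

    def __init__(self, patience: int = 30, min_delta: float = 1e-4, restore_best: bool = True):
        self.patience, self.min_delta, self.restore_best = patience, min_delta, restore_best
        self.best = -np.inf
        self.best_state = None
        self.best_epoch = -1
        self.wait = 0
        self.stopped = False

    def step(self, metric: float, model, epoch: int) -> bool:
        if metric > self.best + self.min_delta:
            self.best = metric
            self.best_epoch = epoch
            self.wait = 0
            if self.restore_best:
                self.best_state = model.state_dict()
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.stopped = True
        return self.stopped

    def finalize(self, model):
        if self.restore_best and self.best_state is not None:
            model.load_state_dict(self.best_state)
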