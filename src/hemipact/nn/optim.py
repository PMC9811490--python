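"""Adam optimizer with decoupled-from-loss L2 regularization.

The L2 term (coefficient ``l2``) is added to the gradient before the
moment updates, matching the classical "weight decay as L2 penalty"
convention.  New parameters can be adopted mid-run (progressive model
growth) via ``add_parameters``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    def __init__(self, parameters, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8, l2: float = 0.0):
        self.params = list(parameters)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2 = l2
        self.state = {id(p): {"m": np.zeros_like(p.data), "v": np.zeros_like(p.data), "t": 0} for p in self.params}

    def add_parameters(self, parameters) -> None:
        for p in parameters:
            if id(p) not in self.state:
                self.params.append(p)
                self.state[id(p)] = {"m": np.zeros_like(p.data), "v": np.zeros_like(p.data), "t": 0}

    def step(self) -> None:
        for p in self.params:
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            if self.l2:
                g = g + self.l2 * p.data
            st = self.state[id(p)]
            st["t"] += 1
            st["m"] = self.b1 * st["m"] + (1 - self.b1) * g
            st["v"] = self.b2 * st["v"] + (1 - self.b2) * g * g
            mhat = st["m"] / (1 - self.b1 ** st["t"])
            vhat = st["v"] / (1 - self.b2 ** st["t"])
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer's learning rate when the
    monitored loss stops improving for ``patience`` evaluations."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 10, min_lr: float = 1e-7):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> None:
        if loss < self.best - 1e-12:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
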