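"""Stochastic gradient descent with classical momentum and weight decay.

Update rule (per parameter, decoupled from nothing — decay enters the
gradient as an L2 term, the standard SGD formulation):

    v <- momentum * v + grad + weight_decay * w
    w <- w - lr * v
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["SGD"]


class SGD:
    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
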