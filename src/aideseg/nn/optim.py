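"""Gradient-descent optimizers over (weight, grad) array pairs."""

from __future__ import annotations

import numpy as np


class SGD:
    """Plain SGD with optional momentum."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(w) for w, _ in self.params]

    def step(self) -> None:
        for (w, g), v in zip(self.params, self.v):
            v *= self.momentum
            v -= self.lr * g
            w += v


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in self.params]
        self.v = [np.zeros_like(w) for w, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            w -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def make_optimizer(name: str, params, lr: float, **kw):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr=lr, **kw)
    if name == "sgd":
        return SGD(params, lr=lr, **kw)
    raise ValueError(f"unknown optimizer {name!r}")
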