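"""First-order optimizers operating on lists of ``Parameter`` objects."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with the DCGAN-convention betas (0.5, 0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.buf = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, b in zip(self.params, self.buf):
            b *= self.momentum
            b += p.grad
            p.data -= self.lr * b

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
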