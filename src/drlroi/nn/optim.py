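"""Parameter-list optimisers (momentum SGD, Adam) with mutable learning rate."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, parameters, lr: float):
        self.parameters = list(parameters)
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.parameters:
            p.grad[...] = 0.0

    def state_dict(self) -> dict:
        raise NotImplementedError

    def load_state_dict(self, state: dict) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    """Stochastic gradient descent with classical momentum and decoupled-style
    L2 weight decay added to the gradient (the standard coupled formulation)."""

    def __init__(self, parameters, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        super().__init__(parameters, lr)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.parameters]

    def step(self):
        for p, v in zip(self.parameters, self.velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def state_dict(self):
        return {
            "lr": self.lr,
            "momentum": self.momentum,
            "weight_decay": self.weight_decay,
            "velocity": [v.copy() for v in self.velocity],
        }

    def load_state_dict(self, state):
        self.lr = state["lr"]
        self.momentum = state["momentum"]
        self.weight_decay = state["weight_decay"]
        for v, s in zip(self.velocity, state["velocity"]):
            v[...] = s


class Adam(Optimizer):
    def __init__(self, parameters, lr: float, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__(parameters, lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.parameters]
        self.v = [np.zeros_like(p.data) for p in self.parameters]

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.parameters, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        return {
            "lr": self.lr,
            "betas": self.betas,
            "eps": self.eps,
            "weight_decay": self.weight_decay,
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state):
        self.lr = state["lr"]
        self.betas = tuple(state["betas"])
        self.eps = state["eps"]
        self.weight_decay = state["weight_decay"]
        self.t = state["t"]
        for m, s in zip(self.m, state["m"]):
            m[...] = s
        for v, s in zip(self.v, state["v"]):
            v[...] = s
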