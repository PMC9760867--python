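"""Gradient-descent optimizers (Adam, RMSProp) for the sequential network."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, net, lr=0.001):
        self.net = net
        self.lr = float(lr)
        self.state: dict[str, dict] = {}

    def step(self):  # pragma: no cover - interface
        raise NotImplementedError


class Adam(Optimizer):
    """Adam with the usual defaults (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, net, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(net, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, owner, pk in self.net.param_items():
            p = self.net.get_param(owner, pk)
            g = self.net.get_grad(owner, pk)
            s = self.state.setdefault(key, {"m": np.zeros_like(p),
                                            "v": np.zeros_like(p)})
            s["m"] = b1 * s["m"] + (1 - b1) * g
            s["v"] = b2 * s["v"] + (1 - b2) * g * g
            mhat = s["m"] / (1 - b1 ** self.t)
            vhat = s["v"] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSProp(Optimizer):
    """RMSProp with rho=0.9 and eps=1e-7."""

    def __init__(self, net, lr=0.001, rho=0.9, eps=1e-7):
        super().__init__(net, lr)
        self.rho, self.eps = rho, eps

    def step(self):
        for key, owner, pk in self.net.param_items():
            p = self.net.get_param(owner, pk)
            g = self.net.get_grad(owner, pk)
            s = self.state.setdefault(key, {"v": np.zeros_like(p)})
            s["v"] = self.rho * s["v"] + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(s["v"]) + self.eps)


OPTIMIZERS = {"adam": Adam, "rmsprop": RMSProp}
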