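"""Adam optimizer over a network's (optionally group-restricted) parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, network, groups=None, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.network = network
        self.groups = set(groups) if groups is not None else None
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, pname, val in self.network.parameters(self.groups):
            g = layer.grads.get(pname)
            if g is None:
                continue
            m = self.m.setdefault(key, np.zeros_like(val))
            v = self.v.setdefault(key, np.zeros_like(val))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            val -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(val.dtype)

    def zero_grad(self) -> None:
        for _, layer, pname, _ in self.network.parameters(self.groups):
            layer.grads.pop(pname, None)
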