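"""Adam optimizer over a ParamStore (default moment parameters, no decay)."""

from __future__ import annotations

import numpy as np

from .layers import ParamStore


class Adam:
    def __init__(self, store: ParamStore, lr: float = 7.0e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.store = store
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in store.params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in store.params.items()}
        self.t = 0

    def step(self) -> None:
        """Update every parameter that received a gradient this pass."""
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for name, p in self.store.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / b1c
            vhat = self.v[name] / b2c
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
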