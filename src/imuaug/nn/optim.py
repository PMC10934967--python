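"""AdamW with decoupled weight decay."""

from __future__ import annotations

import numpy as np

from .core import Layer, parameters


class AdamW:
    """Adam update with weight decay applied directly to the parameters.

    Defaults match the training recipe used throughout the package:
    lr 1e-3, betas (0.9, 0.999), eps 1e-8, weight decay 0.01.
    """

    def __init__(self, model: Layer, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01) -> None:
        self.param_refs = parameters(model)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.param_refs]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.param_refs]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, (layer, name) in enumerate(self.param_refs):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p = layer.params[name]
            p -= self.lr * self.weight_decay * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
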