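"""Adam optimizer over (layer, parameter-name) references."""

from __future__ import annotations

import numpy as np


class Adam:
    """Standard Adam (Kingma & Ba) with bias correction.

    ``slots`` is an iterable of ``(name, layer, key)`` triples, e.g. the
    output of ``Sequential.named_params()``; gradients are read from
    ``layer.grads[key]`` at each ``step``.
    """

    def __init__(self, slots, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = list(slots)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[key]) for _, layer, key in self.slots]
        self.v = [np.zeros_like(layer.params[key]) for _, layer, key in self.slots]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for idx, (_, layer, key) in enumerate(self.slots):
            g = layer.grads[key]
            m = self.m[idx]
            v = self.v[idx]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            layer.params[key] -= (self.lr * update).astype(layer.params[key].dtype)
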