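"""Adam optimizer with decoupled-from-nothing classic L2 regularization.

The L2 coefficient is added to each gradient as ``grad + l2 * w`` before the
moment updates, matching the usual ``weight_decay`` semantics of Adam in
mainstream frameworks.
"""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr=5e-5, l2=1e-5,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.l2 = l2
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, w in self.params.items():
            g = grads[k] + self.l2 * w
            m = self.m[k]
            v = self.v[k]
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            w -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
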