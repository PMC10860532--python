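"""Adam optimizer (Kingma & Ba) with mutable learning rate.

Moment estimates and the parameter update are kept in float64 regardless
of the network compute dtype: with the linearly decaying learning rate,
late-schedule updates become small enough that float32 state accumulation
visibly degrades convergence, while the cost of float64 optimizer state
is negligible next to the convolutions.
"""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]
        self.v = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = np.asarray(p.grad, dtype=np.float64)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = (p.data.astype(np.float64) - update).astype(
                p.data.dtype, copy=False
            )

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {
            "t": self.t,
            "lr": self.lr,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]
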