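"""Optimizers (decoupled-weight-decay Adam)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay.

    Update per parameter p with gradient g:
        m <- b1 m + (1-b1) g ;  v <- b2 v + (1-b2) g^2
        p <- p - lr (m_hat / (sqrt(v_hat) + eps) + wd * p)
    """

    def __init__(self, params: list[Tensor], lr: float = 5e-5,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> dict:
        out = {"t": np.asarray(self.t), "lr": np.asarray(self.lr)}
        for i in range(len(self.params)):
            out[f"m{i}"] = self.m[i].copy()
            out[f"v{i}"] = self.v[i].copy()
        return out

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        for i in range(len(self.params)):
            self.m[i] = np.asarray(state[f"m{i}"], dtype=np.float64).copy()
            self.v[i] = np.asarray(state[f"v{i}"], dtype=np.float64).copy()
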