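"""Adam optimizer with L2 weight decay."""

from __future__ import annotations

import numpy as np

from .layers import Module, Parameter


class Adam:
    """Adam (Kingma & Ba) with classic L2 regularization added to the gradient.

    Parameters are re-queried from the model at each step so that lazily
    created parameters (e.g. positional embeddings sized on first forward)
    are picked up automatically.
    """

    def __init__(self, model: Module, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._state: dict[int, dict] = {}

    def zero_grad(self) -> None:
        self.model.zero_grad()

    def step(self) -> None:
        for p in self.model.parameters():
            if p.grad is None:
                continue
            st = self._state.get(id(p))
            if st is None:
                st = {"t": 0, "m": np.zeros_like(p.data), "v": np.zeros_like(p.data)}
                self._state[id(p)] = st
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            st["t"] += 1
            st["m"] = self.beta1 * st["m"] + (1 - self.beta1) * g
            st["v"] = self.beta2 * st["v"] + (1 - self.beta2) * g * g
            mhat = st["m"] / (1 - self.beta1 ** st["t"])
            vhat = st["v"] / (1 - self.beta2 ** st["t"])
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
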