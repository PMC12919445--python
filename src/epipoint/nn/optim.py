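"""AdamW optimizer and warm-up/cosine learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["AdamW", "warmup_cosine_lr"]


class AdamW:
    """Decoupled weight decay Adam (Loshchilov & Hutter)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.05):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self._m],
                "v": [v.copy() for v in self._v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self._m = [np.asarray(m).copy() for m in state["m"]]
        self._v = [np.asarray(v).copy() for v in state["v"]]


def warmup_cosine_lr(epoch: float, base_lr: float, warmup_epochs: int,
                     total_epochs: int) -> float:
    """Linear warm-up to ``base_lr`` then cosine decay to zero.

    ``epoch`` may be fractional for per-step scheduling. At the end of
    warm-up the rate equals ``base_lr`` exactly.
    """
    if total_epochs <= 0:
        raise ValueError("total_epochs must be positive")
    if warmup_epochs > 0 and epoch < warmup_epochs:
        return base_lr * epoch / warmup_epochs
    if total_epochs == warmup_epochs:
        return base_lr
    progress = (epoch - warmup_epochs) / (total_epochs - warmup_epochs)
    progress = min(max(progress, 0.0), 1.0)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * progress))
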