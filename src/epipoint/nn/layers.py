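"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

from .autograd import Tensor

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "MLP", "Embedding",
           "Dropout"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight module container with named-parameter traversal.

    Sub-modules and parameters are discovered through instance attributes,
    so definitions read like the torch idiom without the dependency.
    """

    def __init__(self):
        self.training = True

    # mode switches propagate to children
    def train(self) -> "Module":
        for m in self._children():
            m.train()
        self.training = True
        return self

    def eval(self) -> "Module":
        for m in self._children():
            m.eval()
        self.training = False
        return self

    def _children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray],
                        strict: bool = True) -> None:
        own = dict(self.named_parameters())
        mismatched = []
        for name, p in own.items():
            if name not in state:
                if strict:
                    mismatched.append(f"missing: {name}")
                continue
            if state[name].shape != p.data.shape:
                mismatched.append(
                    f"shape mismatch: {name} {state[name].shape} != {p.data.shape}")
                continue
            p.data = np.asarray(state[name], dtype=np.float64).copy()
        if strict:
            for name in state:
                if name not in own:
                    mismatched.append(f"unexpected: {name}")
        if mismatched:
            raise ValueError("incompatible state dict:\n  " + "\n  ".join(mismatched))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False, bias: bool = True):
        super().__init__()
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            # Xavier/Glorot uniform
            limit = np.sqrt(6.0 / (d_in + d_out))
            w = rng.uniform(-limit, limit, size=(d_in, d_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.eps) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout driven by an explicit RNG; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MLP(Module):
    """Stack of linear layers with GELU between (none after the last)."""

    def __init__(self, widths: Sequence[int], rng: np.random.Generator):
        super().__init__()
        if len(widths) < 2:
            raise ValueError("MLP needs at least input and output widths")
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.gelu()
        return x


class Embedding(Module):
    """Lookup table of learnable position vectors (zero-initialized)."""

    def __init__(self, n_rows: int, dim: int):
        super().__init__()
        self.table = Parameter(np.zeros((n_rows, dim)))

    def forward(self, idx: np.ndarray) -> Tensor:
        idx = np.asarray(idx)
        if idx.size and idx.max() >= self.table.shape[0]:
            raise IndexError(
                f"position {int(idx.max())} exceeds table size "
                f"{self.table.shape[0]}; increase max_residues in the config")
        return self.table[idx]
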