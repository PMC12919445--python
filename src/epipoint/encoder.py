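"""Shared pre-norm transformer encoder with rotary position encoding.

Both chains of a complex pass through the *same* 4-block encoder (weight
sharing doubles the data seen by every parameter). Rotary position encoding
(RoPE) rotates each 2-D slice of the query and key vectors by an angle
proportional to the residue's ordinal position, so attention logits depend
only on relative sequence distance. The frequency spectrum is
``theta_i = base**(-2i/d_head)`` with base 2048, matching typical
antigen/antibody chain lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import MLP, Dropout, LayerNorm, Linear, Module, Tensor, concat
from .rhem import ResidueEmbeddingSequence

__all__ = ["EncoderConfig", "rope_angles", "rope_rotate", "MultiHeadSelfAttention",
           "EncoderBlock", "Encoder"]


@dataclass
class EncoderConfig:
    n_blocks: int = 4
    d_model: int = 128
    n_heads: int = 4
    rope_base: float = 2048.0
    mlp_ratio: int = 4
    dropout: float = 0.1
    final_layer_norm: bool = True

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.d_head % 2 != 0:
            raise ValueError("d_head must be even for RoPE (2-D rotations)")
        if self.rope_base <= 0:
            raise ValueError("rope_base must be positive")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


def rope_angles(positions: np.ndarray, d_head: int, base: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """cos/sin tables of shape (R, d_head // 2)."""
    if d_head % 2:
        raise ValueError("d_head must be even")
    i = np.arange(d_head // 2)
    theta = base ** (-2.0 * i / d_head)
    ang = np.asarray(positions, dtype=np.float64)[:, None] * theta[None, :]
    return np.cos(ang), np.sin(ang)


def rope_rotate(x: Tensor | np.ndarray, positions: np.ndarray,
                base: float) -> Tensor:
    """Rotate each 2-D slice (2i, 2i+1) of the last axis by ``m * theta_i``.

    ``x`` has shape (..., R, d_head); position ``m`` is taken from
    ``positions`` along the R axis. Norm-preserving by construction.
    """
    if not isinstance(x, Tensor):
        x = Tensor(x)
    d_head = x.shape[-1]
    cos, sin = rope_angles(positions, d_head, base)
    cos_t, sin_t = Tensor(cos), Tensor(sin)
    even = x[..., 0::2]
    odd = x[..., 1::2]
    rot_even = even * cos_t - odd * sin_t
    rot_odd = even * sin_t + odd * cos_t
    # re-interleave
    shape = x.shape
    half = shape[:-1] + (d_head // 2, 1)
    stacked = concat([rot_even.reshape(*half), rot_odd.reshape(*half)], axis=-1)
    return stacked.reshape(*shape)


class MultiHeadSelfAttention(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.d_model
        self.w_q = Linear(d, d, rng)
        self.w_k = Linear(d, d, rng)
        self.w_v = Linear(d, d, rng)
        self.w_o = Linear(d, d, rng)
        self.dropout = Dropout(cfg.dropout, rng)

    def _split_heads(self, x: Tensor) -> Tensor:
        r = x.shape[0]
        h, dh = self.cfg.n_heads, self.cfg.d_head
        return x.reshape(r, h, dh).swapaxes(0, 1)  # (h, R, dh)

    def forward(self, x: Tensor, positions: np.ndarray,
                return_attention: bool = False):
        cfg = self.cfg
        r = x.shape[0]
        q = self._split_heads(self.w_q(x))
        k = self._split_heads(self.w_k(x))
        v = self._split_heads(self.w_v(x))
        q = rope_rotate(q, positions, cfg.rope_base)
        k = rope_rotate(k, positions, cfg.rope_base)
        scores = (q @ k.T) * (1.0 / np.sqrt(cfg.d_head))   # (h, R, R)
        attn = scores.softmax(axis=-1)
        out = attn @ v                                      # (h, R, dh)
        out = out.swapaxes(0, 1).reshape(r, cfg.d_model)
        out = self.dropout(self.w_o(out))
        if return_attention:
            return out, attn
        return out


class EncoderBlock(Module):
    """Pre-norm block: x + Attn(LN(x)), then + MLP(LN(.))."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.d_model
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(cfg, rng)
        self.ln2 = LayerNorm(d)
        self.mlp = MLP((d, cfg.mlp_ratio * d, d), rng)
        self.dropout = Dropout(cfg.dropout, rng)

    def forward(self, x: Tensor, positions: np.ndarray) -> Tensor:
        x = x + self.attn(self.ln1(x), positions)
        x = x + self.dropout(self.mlp(self.ln2(x)))
        return x


class Encoder(Module):
    """Stack of ``n_blocks`` pre-norm transformer blocks (default 4),
    shared between antigen and antibody chains."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.blocks = [EncoderBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.final_ln = LayerNorm(cfg.d_model) if cfg.final_layer_norm else None

    def forward(self, h: ResidueEmbeddingSequence) -> ResidueEmbeddingSequence:
        x = h.values
        for block in self.blocks:
            x = block(x, h.positions)
        if self.final_ln is not None:
            x = self.final_ln(x)
        return ResidueEmbeddingSequence(values=x, positions=h.positions)
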