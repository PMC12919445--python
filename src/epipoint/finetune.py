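"""Cross-attention decoder and per-residue epitope classification (stage 2).

Antigen residue embeddings query the antibody embeddings through multi-head
cross-attention (no self-attention and no positional rotation inside the
decoder), yielding antibody-aware antigen representations. A small MLP head
maps each to an epitope probability; training minimizes binary
cross-entropy with label smoothing. RHEM and encoder weights are
initialized from the pretraining checkpoint unless training from scratch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augmentation import (AugmentationConfig, jitter_coords_and_normals,
                           random_rotation_pair)
from .encoder import Encoder, EncoderConfig
from .nn import (MLP, AdamW, Dropout, LayerNorm, Linear, Module, Tensor,
                 no_grad, warmup_cosine_lr)
from .pretrain import PretrainModel, chain_inputs_from_features
from .rhem import ChainInputs, Rhem, RhemConfig

logger = logging.getLogger(__name__)

__all__ = ["DecoderConfig", "EpitopePrediction", "CrossAttentionBlock",
           "SiteHead", "EpitopeModel", "bce_loss", "FinetuneConfig",
           "run_finetuning", "predict"]


@dataclass
class DecoderConfig:
    n_heads: int = 4
    d_model: int = 128
    dropout: float = 0.1
    n_decoder_blocks: int = 1
    mlp_ratio: int = 4
    site_hidden: int = 256

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class EpitopePrediction:
    probabilities: np.ndarray           # (R_A,) in [0,1]
    threshold: float
    calls: np.ndarray                   # (R_A,) binary, prob >= threshold
    attention: np.ndarray | None = None  # (heads, R_A, R_B) decoder map

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise ValueError("probabilities must lie in [0,1]")


class CrossAttentionBlock(Module):
    """Antigen queries over antibody keys/values, residual, then MLP.

    Z' = Z + Dropout(Attn(LN(Z), LN(H_B), LN(H_B)))
    Z~ = Z' + Dropout(MLP(LN(Z')))
    """

    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.d_model
        self.ln_q = LayerNorm(d)
        self.ln_kv = LayerNorm(d)
        self.w_q = Linear(d, d, rng)
        self.w_k = Linear(d, d, rng)
        self.w_v = Linear(d, d, rng)
        self.w_o = Linear(d, d, rng)
        self.attn_dropout = Dropout(cfg.dropout, rng)
        self.ln_mlp = LayerNorm(d)
        self.mlp = MLP((d, cfg.mlp_ratio * d, d), rng)
        self.mlp_dropout = Dropout(cfg.dropout, rng)

    def forward(self, z_a: Tensor, h_b: Tensor, return_attention: bool = False):
        cfg = self.cfg
        r_a, r_b = z_a.shape[0], h_b.shape[0]
        h, dh = cfg.n_heads, cfg.d_head
        q = self.w_q(self.ln_q(z_a)).reshape(r_a, h, dh).swapaxes(0, 1)
        kv_norm = self.ln_kv(h_b)
        k = self.w_k(kv_norm).reshape(r_b, h, dh).swapaxes(0, 1)
        v = self.w_v(kv_norm).reshape(r_b, h, dh).swapaxes(0, 1)
        scores = (q @ k.T) * (1.0 / np.sqrt(dh))   # (h, R_A, R_B)
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).swapaxes(0, 1).reshape(r_a, cfg.d_model)
        z_prime = z_a + self.attn_dropout(self.w_o(ctx))
        z_tilde = z_prime + self.mlp_dropout(self.mlp(self.ln_mlp(z_prime)))
        if return_attention:
            return z_tilde, attn
        return z_tilde


class SiteHead(Module):
    """Two 256-wide fully connected layers (LN, ReLU, Dropout after each),
    then a final linear projection and a sigmoid."""

    def __init__(self, d_model: int, rng: np.random.Generator,
                 hidden: int = 256, dropout: float = 0.1):
        super().__init__()
        self.fc1 = Linear(d_model, hidden, rng)
        self.ln1 = LayerNorm(hidden)
        self.drop1 = Dropout(dropout, rng)
        self.fc2 = Linear(hidden, hidden, rng)
        self.ln2 = LayerNorm(hidden)
        self.drop2 = Dropout(dropout, rng)
        self.out = Linear(hidden, 1, rng)

    def forward(self, z: Tensor) -> Tensor:
        x = self.drop1(self.ln1(self.fc1(z)).relu())
        x = self.drop2(self.ln2(self.fc2(x)).relu())
        return self.out(x).sigmoid().reshape(-1)


class EpitopeModel(Module):
    """Full stack: RHEM -> shared encoder (both chains) -> cross-attention
    decoder -> site head."""

    def __init__(self, rhem_cfg: RhemConfig, enc_cfg: EncoderConfig,
                 dec_cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        if dec_cfg.d_model != enc_cfg.d_model:
            raise ValueError("decoder width must match encoder width")
        self.rhem = Rhem(rhem_cfg, rng)
        self.encoder = Encoder(enc_cfg, rng)
        self.decoder_blocks = [CrossAttentionBlock(dec_cfg, rng)
                               for _ in range(dec_cfg.n_decoder_blocks)]
        self.site_head = SiteHead(dec_cfg.d_model, rng, dec_cfg.site_hidden,
                                  dec_cfg.dropout)

    def load_pretrained(self, pretrained: PretrainModel | dict) -> None:
        """Initialize RHEM and encoder from a stage-1 model or state dict."""
        state = (pretrained.state_dict() if isinstance(pretrained, Module)
                 else dict(pretrained))
        sub = {}
        for name, value in state.items():
            if name.startswith(("rhem.", "encoder.")):
                sub[name] = value
        own = Module.state_dict(self)
        merged = {n: sub.get(n, own[n]) for n in own}
        mismatch = [n for n in sub
                    if n in own and own[n].shape != np.asarray(sub[n]).shape]
        if mismatch:
            raise ValueError("pretrained checkpoint incompatible; mismatched "
                             f"shapes for: {mismatch}")
        self.load_state_dict(merged)

    def forward(self, antigen: ChainInputs, antibody: ChainInputs,
                return_attention: bool = False):
        h_a = self.encoder(self.rhem(antigen))
        h_b = self.encoder(self.rhem(antibody))
        z = h_a.values
        attn = None
        for block in self.decoder_blocks:
            if return_attention:
                z, attn = block(z, h_b.values, return_attention=True)
            else:
                z = block(z, h_b.values)
        probs = self.site_head(z)
        if return_attention:
            return probs, attn
        return probs


def bce_loss(y_hat: Tensor, y: np.ndarray, smoothing: float = 0.0) -> Tensor:
    """Mean binary cross-entropy with label smoothing.

    Targets are mapped ``y -> y * (1 - eps) + eps / 2`` before the loss.
    """
    if not 0.0 <= smoothing < 1.0:
        raise ValueError("smoothing must be in [0,1)")
    t = np.asarray(y, dtype=np.float64) * (1.0 - smoothing) + smoothing / 2.0
    t = Tensor(t)
    one = Tensor(1.0)
    return -(t * y_hat.log() + (one - t) * (one - y_hat).log()).mean()


# ----------------------------------------------------------------- training

@dataclass
class FinetuneConfig:
    epochs: int = 40
    warmup_epochs: int = 10
    batch_size: int = 4
    lr: float = 1e-4
    weight_decay: float = 0.05
    label_smoothing: float = 0.1
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    augment: bool = True
    from_scratch: bool = False
    seed: int = 0


def _augmented_inputs(sample, cfg: FinetuneConfig, rng) -> tuple[ChainInputs, ChainInputs]:
    ag_atoms, ab_atoms = sample.antigen_atoms, sample.antibody_atoms
    if cfg.augment:
        if cfg.augmentation.rotate:
            ag_atoms, ab_atoms, _, _ = random_rotation_pair(ag_atoms, ab_atoms, rng)
        ag_atoms = jitter_coords_and_normals(ag_atoms, cfg.augmentation, rng)
        ab_atoms = jitter_coords_and_normals(ab_atoms, cfg.augmentation, rng)
    ag = chain_inputs_from_features(ag_atoms, sample.antigen_starts,
                                    sample.antigen_residues, sample.antigen_plm)
    ab = chain_inputs_from_features(ab_atoms, sample.antibody_starts,
                                    sample.antibody_residues, sample.antibody_plm)
    return ag, ab


def run_finetuning(dataset, pretrained: PretrainModel | dict | None,
                   cfg: FinetuneConfig,
                   rhem_cfg: RhemConfig | None = None,
                   enc_cfg: EncoderConfig | None = None,
                   dec_cfg: DecoderConfig | None = None,
                   log: list | None = None) -> EpitopeModel:
    """Stage-2 loop: epitope labels are fixed *before* augmentation (the
    independent rotations destroy the binding pose on purpose); the whole
    stack trains end to end."""
    if len(dataset) == 0:
        raise ValueError("empty finetuning dataset")
    rng = np.random.default_rng(cfg.seed)
    model = EpitopeModel(rhem_cfg or RhemConfig(), enc_cfg or EncoderConfig(),
                         dec_cfg or DecoderConfig(),
                         np.random.default_rng(rng.integers(2 ** 31)))
    if pretrained is not None and not cfg.from_scratch:
        model.load_pretrained(pretrained)
    model.train()
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    order = np.arange(len(dataset))
    step = 0
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.lr = warmup_cosine_lr(epoch + start / len(order), cfg.lr,
                                      cfg.warmup_epochs, cfg.epochs)
            opt.zero_grad()
            for idx in batch:
                sample = dataset[idx]
                ag, ab = _augmented_inputs(sample, cfg, rng)
                probs = model(ag, ab)
                loss = bce_loss(probs, sample.labels.labels, cfg.label_smoothing)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"finetuning diverged at epoch {epoch} step {step}")
                loss.backward()
                if log is not None:
                    log.append({"epoch": epoch, "step": step, "lr": opt.lr,
                                "loss": float(loss.data)})
            opt.step()
            step += 1
    model.eval()
    return model


def predict(antigen: ChainInputs, antibody: ChainInputs, model: EpitopeModel,
            threshold: float = 0.5) -> EpitopePrediction:
    """Deterministic forward pass (no augmentation, eval mode); exports the
    decoder cross-attention map for interface analysis."""
    model.eval()
    with no_grad():
        probs, attn = model(antigen, antibody, return_attention=True)
    probs = probs.data
    return EpitopePrediction(
        probabilities=probs,
        threshold=float(threshold),
        calls=(probs >= threshold).astype(np.int64),
        attention=None if attn is None else attn.data,
    )
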