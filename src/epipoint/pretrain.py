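"""Masked-feature self-supervised pretraining (stage 1).

Half of the residues on each chain are masked independently; a masked
residue's amino-acid one-hot, solvent accessibility and PSSM blocks are
jointly replaced by zeros (20% of masked residues) or by uniform draws from
the feature range [0,1] (80%; the amino-acid block becomes a random
one-hot). Neighbour composition is never corrupted. Three parallel heads
reconstruct the original blocks from the encoder output, and the loss
(cross-entropy for the type, MSE for the regressions, weighted sum) is
taken over masked residues only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augmentation import (AugmentationConfig, jitter_coords_and_normals,
                           jitter_residue_features)
from .encoder import Encoder, EncoderConfig
from .features import AtomFeatureMatrix, ResidueFeatureMatrix
from .nn import AdamW, Dropout, Linear, Module, Tensor, no_grad, warmup_cosine_lr
from .rhem import ChainInputs, Rhem, RhemConfig

logger = logging.getLogger(__name__)

__all__ = ["MaskingSpec", "PretrainLossWeights", "MaskedBatch", "sample_mask",
           "corrupt", "ReconstructionHead", "PretrainModel", "pretrain_loss",
           "PretrainConfig", "run_pretraining"]


@dataclass
class MaskingSpec:
    mask_fraction: float = 0.5
    zero_fill_prob: float = 0.2
    random_fill_prob: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must be in [0,1]")
        if abs(self.zero_fill_prob + self.random_fill_prob - 1.0) > 1e-12:
            raise ValueError("zero_fill_prob + random_fill_prob must equal 1")


@dataclass
class PretrainLossWeights:
    lambda_aa: float = 1.0
    lambda_sol: float = 1.0
    lambda_pssm: float = 1.0

    def __post_init__(self):
        if min(self.lambda_aa, self.lambda_sol, self.lambda_pssm) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.lambda_aa == self.lambda_sol == self.lambda_pssm == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class MaskedBatch:
    corrupted: ResidueFeatureMatrix
    mask_indices: np.ndarray
    original: ResidueFeatureMatrix


def sample_mask(n_residues: int, spec: MaskingSpec,
                rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(mask_fraction) selection of residue indices."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    return np.flatnonzero(rng.random(n_residues) < spec.mask_fraction)


def corrupt(features: ResidueFeatureMatrix, mask: np.ndarray, spec: MaskingSpec,
            rng: np.random.Generator) -> MaskedBatch:
    """Corrupt the three target blocks of the masked residues.

    The zero-vs-random decision is a single Bernoulli draw per masked
    residue and applies jointly to all three blocks.
    """
    out = features.copy()
    mask = np.asarray(mask, dtype=np.int64)
    for j in mask:
        if rng.random() < spec.zero_fill_prob:
            out.aa_type[j] = 0.0
            out.solvent_acc[j] = 0.0
            out.pssm[j] = 0.0
        else:
            out.aa_type[j] = 0.0
            out.aa_type[j, rng.integers(20)] = 1.0
            out.solvent_acc[j] = rng.random(2)
            out.pssm[j] = rng.random(20)
    return MaskedBatch(corrupted=out, mask_indices=mask, original=features)


class ReconstructionHead(Module):
    """Linear -> GELU -> Dropout -> Linear (one per reconstruction target)."""

    def __init__(self, d_model: int, d_out: int, dropout: float,
                 rng: np.random.Generator, d_hidden: int | None = None):
        super().__init__()
        d_hidden = d_hidden or d_model
        self.fc1 = Linear(d_model, d_hidden, rng)
        self.dropout = Dropout(dropout, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def forward(self, h: Tensor) -> Tensor:
        return self.fc2(self.dropout(self.fc1(h).gelu()))


class PretrainModel(Module):
    """RHEM + shared encoder + three reconstruction heads."""

    def __init__(self, rhem_cfg: RhemConfig, enc_cfg: EncoderConfig,
                 rng: np.random.Generator, head_dropout: float = 0.1):
        super().__init__()
        self.rhem = Rhem(rhem_cfg, rng)
        self.encoder = Encoder(enc_cfg, rng)
        d = enc_cfg.d_model
        self.head_aa = ReconstructionHead(d, 20, head_dropout, rng)
        self.head_sol = ReconstructionHead(d, 2, head_dropout, rng)
        self.head_pssm = ReconstructionHead(d, 20, head_dropout, rng)

    def forward(self, inputs: ChainInputs) -> tuple[Tensor, Tensor, Tensor]:
        h = self.encoder(self.rhem(inputs))
        return (self.head_aa(h.values), self.head_sol(h.values),
                self.head_pssm(h.values))


def _masked_cross_entropy(logits: Tensor, onehot: np.ndarray,
                          mask: np.ndarray) -> Tensor:
    sel = logits[mask]
    shifted = sel - Tensor(sel.data.max(axis=-1, keepdims=True))
    log_z = shifted.exp().sum(axis=-1, keepdims=True).log()
    log_probs = shifted - log_z
    return -(log_probs * Tensor(onehot[mask])).sum() * (1.0 / len(mask))


def pretrain_loss(preds: tuple[Tensor, Tensor, Tensor],
                  original: ResidueFeatureMatrix, mask: np.ndarray,
                  weights: PretrainLossWeights | None = None
                  ) -> tuple[Tensor, dict[str, float]]:
    """Weighted reconstruction loss over masked residues only.

    Returns the total loss tensor plus a dict of the unweighted components.
    """
    weights = weights or PretrainLossWeights()
    mask = np.asarray(mask, dtype=np.int64)
    if len(mask) == 0:
        logger.warning("empty mask: pretraining loss is 0 for this batch")
        zero = Tensor(0.0)
        return zero, {"aa": 0.0, "sol": 0.0, "pssm": 0.0}
    aa_logits, sol_pred, pssm_pred = preds
    l_aa = _masked_cross_entropy(aa_logits, original.aa_type, mask)
    d_sol = sol_pred[mask] - Tensor(original.solvent_acc[mask])
    l_sol = (d_sol * d_sol).mean()
    d_pssm = pssm_pred[mask] - Tensor(original.pssm[mask])
    l_pssm = (d_pssm * d_pssm).mean()
    total = (weights.lambda_aa * l_aa + weights.lambda_sol * l_sol
             + weights.lambda_pssm * l_pssm)
    return total, {"aa": float(l_aa.data), "sol": float(l_sol.data),
                   "pssm": float(l_pssm.data)}


# ----------------------------------------------------------------- training

@dataclass
class PretrainConfig:
    epochs: int = 20
    warmup_epochs: int = 2
    batch_size: int = 4              # complexes per optimizer step
    lr: float = 1e-4
    weight_decay: float = 0.05
    masking: MaskingSpec = field(default_factory=MaskingSpec)
    loss_weights: PretrainLossWeights = field(default_factory=PretrainLossWeights)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    augment: bool = True
    seed: int = 0


def chain_inputs_from_features(atom_fm: AtomFeatureMatrix,
                               residue_starts: np.ndarray,
                               res_fm: ResidueFeatureMatrix,
                               plm: np.ndarray | None = None) -> ChainInputs:
    return ChainInputs(atom_matrix=atom_fm.as_matrix(),
                       residue_starts=residue_starts,
                       residue_features=res_fm.as_matrix(), plm=plm)


def _pretrain_step_chains(sample) -> list[tuple[AtomFeatureMatrix, np.ndarray,
                                                ResidueFeatureMatrix]]:
    """Both chains of a complex, processed separately without interaction."""
    return [(sample.antigen_atoms, sample.antigen_starts, sample.antigen_residues),
            (sample.antibody_atoms, sample.antibody_starts, sample.antibody_residues)]


def run_pretraining(dataset, cfg: PretrainConfig,
                    model: PretrainModel | None = None,
                    log: list | None = None) -> PretrainModel:
    """Stage-1 training loop (AdamW, linear warm-up then cosine decay).

    ``dataset`` is a sequence of :class:`epipoint.dataset.ComplexSample`.
    The loss per chain is the masked-reconstruction objective; complexes
    are split into chains that never interact during pretraining.
    """
    from .augmentation import random_rotation_pair

    if len(dataset) == 0:
        raise ValueError("empty pretraining dataset")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = PretrainModel(RhemConfig(), EncoderConfig(),
                              np.random.default_rng(rng.integers(2 ** 31)))
    model.train()
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    order = np.arange(len(dataset))
    step = 0
    steps_per_epoch = max(1, int(np.ceil(len(dataset) / cfg.batch_size)))
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.lr = warmup_cosine_lr(epoch + (start / len(order)), cfg.lr,
                                      cfg.warmup_epochs, cfg.epochs)
            opt.zero_grad()
            batch_loss = 0.0
            for idx in batch:
                sample = dataset[idx]
                ag_atoms, ab_atoms = sample.antigen_atoms, sample.antibody_atoms
                if cfg.augment:
                    if cfg.augmentation.rotate:
                        ag_atoms, ab_atoms, _, _ = random_rotation_pair(
                            ag_atoms, ab_atoms, rng)
                    ag_atoms = jitter_coords_and_normals(ag_atoms,
                                                         cfg.augmentation, rng)
                    ab_atoms = jitter_coords_and_normals(ab_atoms,
                                                         cfg.augmentation, rng)
                chains = [(ag_atoms, sample.antigen_starts, sample.antigen_residues),
                          (ab_atoms, sample.antibody_starts, sample.antibody_residues)]
                for atoms, starts, res in chains:
                    if cfg.augment:
                        res = jitter_residue_features(res, cfg.augmentation,
                                                      rng, stage="pretrain")
                    mask = sample_mask(res.n_residues, cfg.masking, rng)
                    masked = corrupt(res, mask, cfg.masking, rng)
                    inputs = chain_inputs_from_features(atoms, starts,
                                                        masked.corrupted)
                    preds = model(inputs)
                    loss, comps = pretrain_loss(preds, masked.original,
                                                masked.mask_indices,
                                                cfg.loss_weights)
                    if loss.requires_grad:
                        loss.backward()
                    total = float(loss.data)
                    if not np.isfinite(total):
                        raise FloatingPointError(
                            f"pretraining diverged at epoch {epoch} step {step}: "
                            f"loss={total}, components={comps}")
                    batch_loss += total
                    if log is not None:
                        log.append({"epoch": epoch, "step": step,
                                    "lr": opt.lr, "loss": total, **comps})
            opt.step()
            step += 1
    model.eval()
    return model
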