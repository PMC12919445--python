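"""Residue-aware hierarchical embedding.

Atoms of each residue are encoded by a shared per-atom MLP and max-pooled
into a residue-level atomic vector (a lightweight PointNet: permutation
invariant within the residue). This vector is concatenated with the fused
residue features (physicochemical features, optionally reduced jointly with
a PLM embedding) and passed through a second MLP; a learnable absolute
positional vector is added to give the final residue embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import MLP, Dropout, Embedding, Linear, Module, Tensor, concat

__all__ = ["RhemConfig", "ResidueEmbeddingSequence", "Rhem", "ChainInputs"]


@dataclass
class RhemConfig:
    atom_mlp_widths: tuple[int, ...] = (11, 32, 64)
    embed_mlp_widths: tuple[int, ...] = ()   # derived in __post_init__ if empty
    d_model: int = 128
    dropout: float = 0.1
    max_residues: int = 2048
    residue_feature_dim: int = 62
    use_plm: bool = False
    plm_dim: int = 480
    fused_dim: int = 62        # output width of the PLM fusion MLP
    center_coords: bool = True  # subtract per-chain centroid from coordinates

    def __post_init__(self):
        if self.atom_mlp_widths[0] != 11:
            raise ValueError("atom MLP must take the 11-dim atom vector")
        if not self.embed_mlp_widths:
            d_in = self.atom_mlp_widths[-1] + self.fused_dim
            self.embed_mlp_widths = (d_in, self.d_model, self.d_model)
        if self.embed_mlp_widths[-1] != self.d_model:
            raise ValueError("embed MLP must end at d_model")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")

    @property
    def d_atom(self) -> int:
        return self.atom_mlp_widths[-1]


@dataclass
class ChainInputs:
    """Numeric model inputs for one chain."""

    atom_matrix: np.ndarray       # (N, 11)
    residue_starts: np.ndarray    # (R,)
    residue_features: np.ndarray  # (R, 62)
    plm: np.ndarray | None = None

    def __post_init__(self):
        self.atom_matrix = np.asarray(self.atom_matrix, dtype=np.float64)
        self.residue_starts = np.asarray(self.residue_starts, dtype=np.int64)
        self.residue_features = np.asarray(self.residue_features, dtype=np.float64)
        if self.atom_matrix.shape[1] != 11:
            raise ValueError("atom matrix must have 11 columns")

    @property
    def n_residues(self) -> int:
        return len(self.residue_starts)


@dataclass
class ResidueEmbeddingSequence:
    """Ordered residue embeddings flowing through encoder and decoder."""

    values: Tensor                # (R, d_model)
    positions: np.ndarray         # (R,) 0-based ordinals

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


class Rhem(Module):
    def __init__(self, cfg: RhemConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.atom_mlp = MLP(cfg.atom_mlp_widths, rng)
        if cfg.use_plm:
            d_in = cfg.residue_feature_dim + cfg.plm_dim
            self.fuse_a = Linear(d_in, cfg.fused_dim * 2, rng)
            self.fuse_b = Linear(cfg.fused_dim * 2, cfg.fused_dim, rng)
            self.fuse_dropout = Dropout(cfg.dropout, rng)
        self.embed_mlp = MLP(cfg.embed_mlp_widths, rng)
        self.pos_table = Embedding(cfg.max_residues, cfg.d_model)

    # ------------------------------------------------------------ spec ops
    def pointnet_aggregate(self, atom_features: Tensor | np.ndarray) -> Tensor:
        """Shared per-atom MLP followed by element-wise max over atoms.

        ``atom_features`` is the (n_j, 11) block of one residue; the output
        is invariant to any permutation or duplication of its rows.
        """
        x = atom_features if isinstance(atom_features, Tensor) else Tensor(atom_features)
        if x.shape[0] == 0:
            raise ValueError("residue with no atoms")
        return self.atom_mlp(x).max(axis=0)

    def fuse_residue_features(self, f_res: Tensor, f_plm: Tensor | None) -> Tensor:
        """Joint reduction of physicochemical + PLM features; identity
        (``f_res`` verbatim) when no PLM embedding is supplied."""
        if f_plm is None:
            return f_res
        if not self.cfg.use_plm:
            raise ValueError("model was built without a PLM fusion branch")
        x = concat([f_res, f_plm], axis=-1)
        return self.fuse_dropout(self.fuse_b(self.fuse_a(x).gelu()))

    def residue_embed(self, h_atom: Tensor, f_fused: Tensor,
                      positions: np.ndarray) -> Tensor:
        positions = np.atleast_1d(np.asarray(positions))
        if positions.max(initial=-1) >= self.cfg.max_residues:
            raise ValueError(
                f"residue position {int(positions.max())} >= max_residues "
                f"{self.cfg.max_residues}; increase RhemConfig.max_residues")
        x = concat([h_atom, f_fused], axis=-1)
        return self.embed_mlp(x) + self.pos_table(positions)

    # ------------------------------------------------------------- forward
    def forward(self, inputs: ChainInputs) -> ResidueEmbeddingSequence:
        atom_matrix = inputs.atom_matrix
        if self.cfg.center_coords:
            atom_matrix = atom_matrix.copy()
            atom_matrix[:, :3] -= atom_matrix[:, :3].mean(axis=0)
        per_atom = self.atom_mlp(Tensor(atom_matrix))  # (N, d_atom)
        r = inputs.n_residues
        starts = inputs.residue_starts
        ends = np.append(starts[1:], atom_matrix.shape[0])
        pooled = [per_atom[int(lo):int(hi)].max(axis=0, keepdims=True)
                  for lo, hi in zip(starts, ends)]
        h_atom = concat(pooled, axis=0)  # (R, d_atom)
        f_res = Tensor(inputs.residue_features)
        f_plm = Tensor(inputs.plm) if inputs.plm is not None else None
        f_fused = self.fuse_residue_features(f_res, f_plm)
        positions = np.arange(r)
        values = self.residue_embed(h_atom, f_fused, positions)
        return ResidueEmbeddingSequence(values=values, positions=positions)
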