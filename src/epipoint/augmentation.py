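"""Training-time stochastic structure and feature perturbations.

Three augmentations: Gaussian jitter of atomic coordinates and surface
normals, independent Haar-uniform rotations of the antigen and antibody,
and (pretraining only) Gaussian noise on the continuous residue features
(neighbour composition and solvent accessibility).

Epitope labels are always computed *before* augmentation and reused:
independent per-chain rotations destroy the binding pose, so labels must
never be re-derived from augmented coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import special_ortho_group

from .features import AtomFeatureMatrix, ResidueFeatureMatrix

__all__ = ["AugmentationConfig", "jitter_coords_and_normals",
           "random_rotation_pair", "jitter_residue_features"]


@dataclass
class AugmentationConfig:
    coord_noise_sigma: float = 0.1        # A
    normal_noise_sigma: float = 0.05
    rotate: bool = True
    residue_feature_noise_sigma: float = 0.02
    pretrain_only_feature_noise: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.coord_noise_sigma, self.normal_noise_sigma,
               self.residue_feature_noise_sigma) < 0:
            raise ValueError("noise sigmas must be >= 0")


def jitter_coords_and_normals(atoms: AtomFeatureMatrix, cfg: AugmentationConfig,
                              rng: np.random.Generator) -> AtomFeatureMatrix:
    """Add i.i.d. zero-mean Gaussian noise to coordinates and normals;
    normals are renormalized to unit length afterwards."""
    coords = atoms.coords
    normals = atoms.normal
    if cfg.coord_noise_sigma > 0:
        coords = coords + rng.normal(0.0, cfg.coord_noise_sigma, coords.shape)
    if cfg.normal_noise_sigma > 0:
        normals = normals + rng.normal(0.0, cfg.normal_noise_sigma, normals.shape)
        normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return AtomFeatureMatrix(coords, atoms.atom_type.copy(), normals)


def random_rotation_pair(antigen_atoms: AtomFeatureMatrix,
                         antibody_atoms: AtomFeatureMatrix,
                         rng: np.random.Generator
                         ) -> tuple[AtomFeatureMatrix, AtomFeatureMatrix,
                                    np.ndarray, np.ndarray]:
    """Apply independent Haar-uniform rotations to each chain.

    Coordinates and normals rotate together (both are geometric vectors).
    The two rotation matrices are returned for testability.
    """
    rot_ag = special_ortho_group.rvs(3, random_state=rng)
    rot_ab = special_ortho_group.rvs(3, random_state=rng)

    def apply(atoms: AtomFeatureMatrix, rot: np.ndarray) -> AtomFeatureMatrix:
        return AtomFeatureMatrix(atoms.coords @ rot.T, atoms.atom_type.copy(),
                                 atoms.normal @ rot.T)

    return apply(antigen_atoms, rot_ag), apply(antibody_atoms, rot_ab), rot_ag, rot_ab


def jitter_residue_features(res: ResidueFeatureMatrix, cfg: AugmentationConfig,
                            rng: np.random.Generator,
                            stage: str = "pretrain") -> ResidueFeatureMatrix:
    """Gaussian noise on neighbour composition and solvent accessibility.

    The amino-acid one-hot and PSSM blocks are left untouched; results are
    clipped back to [0,1]. Applied only during pretraining when
    ``pretrain_only_feature_noise`` is set.
    """
    if cfg.pretrain_only_feature_noise and stage != "pretrain":
        return res.copy()
    sigma = cfg.residue_feature_noise_sigma
    if sigma == 0:
        return res.copy()
    sol = np.clip(res.solvent_acc + rng.normal(0, sigma, res.solvent_acc.shape),
                  0.0, 1.0)
    comp = np.clip(res.neighbor_comp + rng.normal(0, sigma, res.neighbor_comp.shape),
                   0.0, 1.0)
    return ResidueFeatureMatrix(res.aa_type.copy(), res.pssm.copy(), sol, comp)
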