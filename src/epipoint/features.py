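"""Atomic-level and residue-level input features.

Per atom (11 dims): 3D coordinates, a 5-way element one-hot (C, N, O, S, H)
and a local surface normal estimated by PCA over the k nearest atoms.
Per residue (62 dims): 20-way amino-acid one-hot, a 20-column PSSM profile
(squashed to [0,1]), solvent accessibility (absolute and relative), and the
20-way composition of sequence neighbours within a Calpha radius. Optional
pretrained language-model embeddings (480 antigen / 512 antibody by default)
are consumed from plain numeric tables, never computed here.

All residue feature blocks live in [0,1] so that masked-feature corruption
can draw uniform replacements from a common range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure_io import (AA_INDEX, ALLOWED_ELEMENTS, STANDARD_AA,
                           THREE_TO_ONE, ChainStructure, ComplexStructure)

logger = logging.getLogger(__name__)

ATOM_FEATURE_DIM = 11
RESIDUE_FEATURE_DIM = 62
DEFAULT_PLM_DIM_ANTIGEN = 480
DEFAULT_PLM_DIM_ANTIBODY = 512

#: Theoretical maximum accessible surface area per residue (A^2),
#: Tien et al. 2013, used for relative accessibility.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
_GLOBAL_MAX_ASA = max(MAX_ASA.values())

_ONE_LETTER_ORDER = [THREE_TO_ONE[a] for a in STANDARD_AA]


@dataclass
class AtomFeatureMatrix:
    """Per-atom inputs: coordinates, element one-hot, surface normal."""

    coords: np.ndarray      # (N, 3)
    atom_type: np.ndarray   # (N, 5) one-hot over (C, N, O, S, H)
    normal: np.ndarray      # (N, 3) unit vectors

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.atom_type = np.asarray(self.atom_type, dtype=np.float64)
        self.normal = np.asarray(self.normal, dtype=np.float64)
        n = self.coords.shape[0]
        if self.atom_type.shape != (n, 5) or self.normal.shape != (n, 3):
            raise ValueError("inconsistent atom feature shapes")
        if not np.allclose(self.atom_type.sum(axis=1), 1.0):
            raise ValueError("atom_type rows must be one-hot")
        norms = np.linalg.norm(self.normal, axis=1)
        if n and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals must be unit length")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def as_matrix(self) -> np.ndarray:
        out = np.concatenate([self.coords, self.atom_type, self.normal], axis=1)
        assert out.shape[1] == ATOM_FEATURE_DIM
        return out


@dataclass
class ResidueFeatureMatrix:
    """Per-residue physicochemical features (4 blocks, 62 columns total)."""

    aa_type: np.ndarray        # (R, 20) one-hot
    pssm: np.ndarray           # (R, 20) in [0,1]
    solvent_acc: np.ndarray    # (R, 2): absolute (scaled), relative
    neighbor_comp: np.ndarray  # (R, 20) rows sum to 1

    def __post_init__(self):
        self.aa_type = np.asarray(self.aa_type, dtype=np.float64)
        self.pssm = np.asarray(self.pssm, dtype=np.float64)
        self.solvent_acc = np.asarray(self.solvent_acc, dtype=np.float64)
        self.neighbor_comp = np.asarray(self.neighbor_comp, dtype=np.float64)
        r = self.aa_type.shape[0]
        if (self.pssm.shape != (r, 20) or self.solvent_acc.shape != (r, 2)
                or self.neighbor_comp.shape != (r, 20)):
            raise ValueError("inconsistent residue feature shapes")
        if not np.allclose(self.aa_type.sum(axis=1), 1.0):
            raise ValueError("aa_type rows must be one-hot")
        if not (np.isfinite(self.solvent_acc).all() and (self.solvent_acc >= 0).all()):
            raise ValueError("solvent accessibility must be finite and >= 0")

    @property
    def n_residues(self) -> int:
        return self.aa_type.shape[0]

    def as_matrix(self) -> np.ndarray:
        out = np.concatenate([self.aa_type, self.pssm, self.solvent_acc,
                              self.neighbor_comp], axis=1)
        assert out.shape[1] == RESIDUE_FEATURE_DIM
        return out

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "ResidueFeatureMatrix":
        m = np.asarray(m, dtype=np.float64)
        if m.shape[1] != RESIDUE_FEATURE_DIM:
            raise ValueError(f"expected {RESIDUE_FEATURE_DIM} columns, got {m.shape[1]}")
        return cls(m[:, :20], m[:, 20:40], m[:, 40:42], m[:, 42:62])

    def copy(self) -> "ResidueFeatureMatrix":
        return ResidueFeatureMatrix(self.aa_type.copy(), self.pssm.copy(),
                                    self.solvent_acc.copy(),
                                    self.neighbor_comp.copy())


@dataclass
class PLMEmbeddingMatrix:
    """Precomputed protein-language-model embeddings, one row per residue."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("PLM embeddings must be a 2-D matrix")

    @property
    def dim(self) -> int:
        return self.values.shape[1]


# ------------------------------------------------------------------ atom level

def compute_atom_type_onehot(chain: ChainStructure) -> np.ndarray:
    onehot = np.zeros((chain.n_atoms, 5))
    for i, elem in enumerate(chain.elements):
        try:
            onehot[i, ALLOWED_ELEMENTS.index(elem)] = 1.0
        except ValueError:
            raise ValueError(
                f"unknown element {elem!r} on atom {chain.atom_names[i]!r} "
                f"(index {i})") from None
    return onehot


def compute_surface_normals(chain: ChainStructure, k_neighbors: int = 16
                            ) -> np.ndarray:
    """Local-PCA surface normals, oriented outward from the chain centroid.

    The normal of an atom is the eigenvector of smallest eigenvalue of the
    covariance of its ``k_neighbors`` nearest atoms; its sign is fixed so
    that it points away from the chain centroid. Rank-deficient
    neighbourhoods fall back to the centroid-outward direction.
    """
    coords = chain.coords
    n = len(coords)
    if n < k_neighbors + 1:
        raise ValueError(f"chain has {n} atoms; need at least {k_neighbors + 1}")
    centroid = coords.mean(axis=0)
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k_neighbors + 1)  # includes the atom itself
    normals = np.empty((n, 3))
    n_degenerate = 0
    for i in range(n):
        nbrs = coords[idx[i]]
        centered = nbrs - nbrs.mean(axis=0)
        cov = centered.T @ centered / len(nbrs)
        evals, evecs = np.linalg.eigh(cov)
        outward = coords[i] - centroid
        if evals[1] < 1e-10 * max(evals[2], 1e-30):  # rank < 2: no plane defined
            n_degenerate += 1
            norm = np.linalg.norm(outward)
            normals[i] = outward / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
            continue
        normal = evecs[:, 0]
        if normal @ outward < 0:
            normal = -normal
        normals[i] = normal
    if n_degenerate:
        logger.warning("surface normals: %d degenerate neighbourhood(s), "
                       "fell back to centroid direction", n_degenerate)
    return normals / np.linalg.norm(normals, axis=1, keepdims=True)


def compute_atom_features(chain: ChainStructure, k_neighbors: int = 16
                          ) -> AtomFeatureMatrix:
    return AtomFeatureMatrix(
        coords=chain.coords.copy(),
        atom_type=compute_atom_type_onehot(chain),
        normal=compute_surface_normals(chain, k_neighbors),
    )


# --------------------------------------------------------------- residue level

def compute_residue_onehot(chain: ChainStructure) -> np.ndarray:
    onehot = np.zeros((chain.n_residues, 20))
    for j, name in enumerate(chain.residue_names):
        if name not in AA_INDEX:
            raise ValueError(f"non-standard residue {name!r} at index {j}; "
                             "clean the structure first")
        onehot[j, AA_INDEX[name]] = 1.0
    return onehot


def squash_pssm(scores: np.ndarray) -> np.ndarray:
    """Logistic squashing of PSI-BLAST log-odds into [0,1]."""
    return 1.0 / (1.0 + np.exp(-np.asarray(scores, dtype=np.float64)))


def parse_psiblast_pssm(path: str | Path) -> tuple[str, np.ndarray]:
    """Read a PSI-BLAST ASCII PSSM; returns (sequence, raw log-odds R x 20).

    Columns are reordered (if necessary) into this package's alphabetical
    3-letter-code order.
    """
    lines = Path(path).read_text().splitlines()
    header_cols: list[str] | None = None
    seq_letters: list[str] = []
    rows: list[list[float]] = []
    for line in lines:
        parts = line.split()
        if header_cols is None:
            # header: 40 single letters (log-odds block then frequency block)
            if len(parts) >= 20 and all(len(p) == 1 and p.isalpha() for p in parts[:20]):
                header_cols = parts[:20]
            continue
        if len(parts) >= 22 and parts[0].isdigit():
            seq_letters.append(parts[1])
            rows.append([float(v) for v in parts[2:22]])
    if header_cols is None or not rows:
        raise ValueError(f"{path}: not a PSI-BLAST ASCII PSSM")
    raw = np.array(rows)
    order = [header_cols.index(letter) for letter in _ONE_LETTER_ORDER]
    return "".join(seq_letters), raw[:, order]


def load_pssm(path: str | Path, chain: ChainStructure) -> np.ndarray:
    """Load a PSI-BLAST PSSM for ``chain``; squashed to [0,1] per column."""
    seq, raw = parse_psiblast_pssm(path)
    chain_seq = chain.sequence
    if len(seq) != len(chain_seq):
        raise ValueError(f"PSSM has {len(seq)} rows but chain has "
                         f"{len(chain_seq)} residues")
    for pos, (a, b) in enumerate(zip(seq, chain_seq), start=1):
        if a != b:
            raise ValueError(f"PSSM sequence mismatch at position {pos}: "
                             f"PSSM {a!r} vs chain {b!r}")
    return squash_pssm(raw)


def pseudo_pssm(chain: ChainStructure) -> np.ndarray:
    """Substitution-matrix profile standing in when no PSI-BLAST run exists.

    Each residue gets the BLOSUM62 row of its amino acid, squashed exactly
    like a real PSSM. Datasets built with it are flagged in their metadata.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    rows = np.empty((chain.n_residues, 20))
    for j, name in enumerate(chain.residue_names):
        letter = THREE_TO_ONE[name]
        rows[j] = [blosum[letter, other] for other in _ONE_LETTER_ORDER]
    return squash_pssm(rows)


def compute_solvent_accessibility(chain: ChainStructure,
                                  point_number: int = 500) -> np.ndarray:
    """Shrake-Rupley accessible surface area per residue (probe 1.4 A).

    Returns an (R, 2) array: column 0 is absolute ASA scaled by the largest
    residue maximum (so it lies in ~[0,1] like every other block), column 1
    is relative accessibility (absolute / residue-specific maximum), clipped
    to [0,1]. Hydrogens are excluded from the calculation.
    """
    import biotite.structure as struc

    heavy = chain.is_heavy
    if not heavy.any():
        raise ValueError("chain has no heavy atoms")
    res_of = chain.atom_residue_index[heavy]
    arr = struc.AtomArray(int(heavy.sum()))
    arr.coord = chain.coords[heavy].astype(np.float32)
    arr.chain_id = np.asarray(chain.chain_ids[res_of], dtype="U4")
    arr.res_id = res_of + 1
    arr.res_name = np.asarray(chain.residue_names[res_of], dtype="U3")
    arr.atom_name = np.asarray(chain.atom_names[heavy], dtype="U6")
    arr.element = np.asarray(chain.elements[heavy], dtype="U2")
    arr.hetero = np.zeros(len(arr), dtype=bool)
    per_atom = struc.sasa(arr, probe_radius=1.4, point_number=point_number,
                          vdw_radii="Single")
    per_atom = np.nan_to_num(per_atom, nan=0.0)
    absolute = np.zeros(chain.n_residues)
    np.add.at(absolute, res_of, per_atom)
    max_asa = np.array([MAX_ASA[name] for name in chain.residue_names])
    relative = np.clip(absolute / max_asa, 0.0, 1.0)
    return np.stack([absolute / _GLOBAL_MAX_ASA, relative], axis=1)


def residue_reference_points(chain: ChainStructure) -> np.ndarray:
    """Calpha coordinate per residue; heavy-atom centroid where CA is absent."""
    points = np.empty((chain.n_residues, 3))
    n_missing = 0
    heavy = chain.is_heavy
    for j in range(chain.n_residues):
        sl = chain.residue_slice(j)
        names = chain.atom_names[sl]
        ca = np.flatnonzero(names == "CA")
        if len(ca):
            points[j] = chain.coords[sl][ca[0]]
        else:
            n_missing += 1
            res_heavy = heavy[sl]
            sub = chain.coords[sl][res_heavy] if res_heavy.any() else chain.coords[sl]
            points[j] = sub.mean(axis=0)
    if n_missing:
        logger.warning("%d residue(s) without CA; used heavy-atom centroids",
                       n_missing)
    return points


def compute_neighbor_composition(chain: ChainStructure, radius: float = 10.0
                                 ) -> np.ndarray:
    """Normalized amino-acid composition of spatial neighbours.

    Residue j's row is the histogram of amino-acid types of residues whose
    Calpha lies within ``radius`` A of residue j's Calpha (j excluded),
    normalized to sum to 1. Isolated residues get a uniform row.
    """
    points = residue_reference_points(chain)
    dist = cdist(points, points)
    np.fill_diagonal(dist, np.inf)
    aa_idx = np.array([AA_INDEX[name] for name in chain.residue_names])
    comp = np.zeros((chain.n_residues, 20))
    n_isolated = 0
    for j in range(chain.n_residues):
        nbrs = aa_idx[dist[j] <= radius]
        if len(nbrs) == 0:
            n_isolated += 1
            comp[j] = 1.0 / 20.0
            continue
        np.add.at(comp[j], nbrs, 1.0)
        comp[j] /= len(nbrs)
    if n_isolated:
        logger.warning("%d residue(s) with no neighbours within %.1f A; "
                       "uniform composition used", n_isolated, radius)
    return comp


# ------------------------------------------------------------------- assembly

@dataclass
class FeatureOptions:
    k_neighbors: int = 16
    neighbor_radius: float = 10.0
    sasa_point_number: int = 500
    antigen_pssm: str | Path | None = None
    antibody_pssm: str | Path | None = None
    antigen_plm: "np.ndarray | str | Path | None" = None
    antibody_plm: "np.ndarray | str | Path | None" = None
    plm_dim_antigen: int = DEFAULT_PLM_DIM_ANTIGEN
    plm_dim_antibody: int = DEFAULT_PLM_DIM_ANTIBODY


def load_plm_table(source: "np.ndarray | str | Path", chain: ChainStructure,
                   expected_dim: int | None = None) -> PLMEmbeddingMatrix:
    if isinstance(source, (str, Path)):
        values = np.loadtxt(source, ndmin=2)
    else:
        values = np.asarray(source, dtype=np.float64)
    if values.shape[0] != chain.n_residues:
        raise ValueError(f"PLM table has {values.shape[0]} rows but chain has "
                         f"{chain.n_residues} residues")
    if expected_dim is not None and values.shape[1] != expected_dim:
        raise ValueError(f"PLM table has {values.shape[1]} columns; "
                         f"expected {expected_dim}")
    return PLMEmbeddingMatrix(values)


def compute_residue_features(chain: ChainStructure,
                             pssm_path: str | Path | None = None,
                             neighbor_radius: float = 10.0,
                             sasa_point_number: int = 500) -> ResidueFeatureMatrix:
    pssm = (load_pssm(pssm_path, chain) if pssm_path is not None
            else pseudo_pssm(chain))
    return ResidueFeatureMatrix(
        aa_type=compute_residue_onehot(chain),
        pssm=pssm,
        solvent_acc=compute_solvent_accessibility(chain, sasa_point_number),
        neighbor_comp=compute_neighbor_composition(chain, neighbor_radius),
    )


def assemble_features(complex: ComplexStructure,
                      options: FeatureOptions | None = None
                      ) -> dict[str, tuple[AtomFeatureMatrix,
                                           ResidueFeatureMatrix,
                                           PLMEmbeddingMatrix | None]]:
    """Compute full model inputs for both chains of a complex.

    Returns ``{"antigen": (atoms, residues, plm), "antibody": (...)}`` with
    the 11/62 widths enforced by the container types.
    """
    options = options or FeatureOptions()
    out = {}
    for role, chain, pssm, plm, plm_dim in (
            ("antigen", complex.antigen, options.antigen_pssm,
             options.antigen_plm, options.plm_dim_antigen),
            ("antibody", complex.antibody, options.antibody_pssm,
             options.antibody_plm, options.plm_dim_antibody)):
        atom_fm = compute_atom_features(chain, options.k_neighbors)
        res_fm = compute_residue_features(chain, pssm, options.neighbor_radius,
                                          options.sasa_point_number)
        plm_fm = None
        if plm is not None:
            plm_fm = load_plm_table(plm, chain, plm_dim)
        out[role] = (atom_fm, res_fm, plm_fm)
    return out
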