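"""Synthetic antigen-antibody complexes for end-to-end testing.

The generator builds each chain as a self-avoiding 3.8 A random walk of
residue centroids with a realistic number of heavy atoms scattered around
each centroid, then translates the antibody toward a surface patch of the
antigen until roughly the requested fraction of antigen residues sits
within the 4.5 A contact cutoff. Labels are always re-derived through
:func:`epipoint.structure_io.label_epitopes` (single source of truth).

A learnable signal is planted in the solvent-accessibility block: epitope
residues are drawn surface-exposed, non-epitope residues mostly buried,
mirroring the biological prior that epitopes lie on the antigen surface.
Amino-acid identity carries no signal. Side-chain chemistry and real
protein geometry are *not* emulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import ComplexSample
from .features import (MAX_ASA, _GLOBAL_MAX_ASA, ResidueFeatureMatrix,
                       compute_atom_features, compute_neighbor_composition,
                       pseudo_pssm)
from .structure_io import (STANDARD_AA, ChainStructure, ComplexStructure,
                           EpitopeLabels, label_epitopes)

__all__ = ["SyntheticSpec", "generate_complex", "generate_dataset",
           "write_fixture_pdb"]

_ELEMENTS = np.array(["C", "N", "O", "S"])
_ELEMENT_PROBS = np.array([0.55, 0.20, 0.20, 0.05])


@dataclass
class SyntheticSpec:
    n_complexes: int = 30
    antigen_residues: tuple[int, int] = (40, 70)
    antibody_residues: tuple[int, int] = (25, 45)
    atoms_per_residue: tuple[int, int] = (4, 14)
    contact_fraction: float = 0.12
    contact_tolerance: float = 0.05
    coordinate_scale: float = 3.8       # A per residue step
    epitope_acc_mean: float = 0.85      # planted relative accessibility
    epitope_acc_sigma: float = 0.08
    background_acc_mean: float = 0.35
    background_acc_sigma: float = 0.15
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.contact_fraction < 1.0:
            raise ValueError("contact_fraction must be in (0,1)")
        for lo, hi in (self.antigen_residues, self.antibody_residues,
                       self.atoms_per_residue):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must be positive and ordered")


def _self_avoiding_walk(n: int, step: float, rng: np.random.Generator,
                        min_sep: float = 3.5, max_tries: int = 200) -> np.ndarray:
    for _ in range(50):  # full restarts
        points = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            for attempt in range(max_tries):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                cand = points[-1] + step * direction
                d = np.linalg.norm(np.array(points) - cand, axis=1)
                if (d >= min_sep).all():
                    points.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            return np.array(points)
    raise RuntimeError("self-avoiding walk failed; enlarge the coordinate "
                       "scale or reduce the residue count")


def _build_chain(n_res: int, spec: SyntheticSpec, chain_id: str,
                 rng: np.random.Generator) -> ChainStructure:
    centroids = _self_avoiding_walk(n_res, spec.coordinate_scale, rng)
    res_names = rng.choice(STANDARD_AA, size=n_res)
    coords, elements, atom_names, starts = [], [], [], []
    n = 0
    for j in range(n_res):
        n_atoms = int(rng.integers(spec.atoms_per_residue[0],
                                   spec.atoms_per_residue[1] + 1))
        starts.append(n)
        # first atom is the CA anchor at the centroid
        coords.append(centroids[j])
        elements.append("C")
        atom_names.append("CA")
        n += 1
        for k in range(n_atoms - 1):
            coords.append(centroids[j] + rng.normal(0.0, 0.8, size=3))
            elem = rng.choice(_ELEMENTS, p=_ELEMENT_PROBS)
            elements.append(elem)
            atom_names.append(f"{elem}{k + 1}")
            n += 1
    return ChainStructure(np.array(coords), np.array(elements),
                          np.array(atom_names), np.array(starts),
                          res_names, np.full(n_res, chain_id))


def _place_antibody(antigen: ChainStructure, antibody: ChainStructure,
                    spec: SyntheticSpec, rng: np.random.Generator
                    ) -> tuple[ChainStructure, EpitopeLabels] | None:
    """Scan the antibody along a centroid-to-surface axis and keep the
    placement whose epitope fraction is closest to the target."""
    ag_centroid = antigen.coords.mean(axis=0)
    # anchor: a residue far from the centroid (a surface patch)
    ca = antigen.coords[antigen.residue_starts]
    dist = np.linalg.norm(ca - ag_centroid, axis=1)
    anchor = ca[rng.choice(np.flatnonzero(dist >= np.quantile(dist, 0.7)))]
    direction = anchor - ag_centroid
    direction /= np.linalg.norm(direction)
    ab_centered = antibody.coords - antibody.coords.mean(axis=0)
    best = None
    for t in np.arange(0.0, 40.0, 0.5):
        moved = ChainStructure(
            ab_centered + anchor + t * direction,
            antibody.elements, antibody.atom_names, antibody.residue_starts,
            antibody.residue_names, antibody.chain_ids, antibody.residue_labels)
        labels = label_epitopes(ComplexStructure(antigen, moved))
        frac = labels.labels.mean()
        gap = abs(frac - spec.contact_fraction)
        if best is None or gap < best[0]:
            best = (gap, moved, labels)
        if frac == 0.0 and t > 10.0:
            break  # moving further away only loses contacts
    gap, moved, labels = best
    if gap > spec.contact_tolerance or labels.labels.sum() == 0:
        return None
    return moved, labels


def _planted_residue_features(chain: ChainStructure, epitope_mask: np.ndarray,
                              spec: SyntheticSpec, rng: np.random.Generator
                              ) -> ResidueFeatureMatrix:
    r = chain.n_residues
    rel = np.where(
        epitope_mask,
        rng.normal(spec.epitope_acc_mean, spec.epitope_acc_sigma, r),
        rng.normal(spec.background_acc_mean, spec.background_acc_sigma, r))
    rel = np.clip(rel, 0.01, 1.0)
    max_asa = np.array([MAX_ASA[name] for name in chain.residue_names])
    absolute = rel * max_asa / _GLOBAL_MAX_ASA
    aa = np.zeros((r, 20))
    from .structure_io import AA_INDEX
    for j, name in enumerate(chain.residue_names):
        aa[j, AA_INDEX[name]] = 1.0
    return ResidueFeatureMatrix(
        aa_type=aa,
        pssm=pseudo_pssm(chain),
        solvent_acc=np.stack([absolute, rel], axis=1),
        neighbor_comp=compute_neighbor_composition(chain),
    )


def generate_complex(spec: SyntheticSpec, rng: np.random.Generator,
                     complex_id: str = "synth", max_retries: int = 20
                     ) -> ComplexSample:
    """One synthetic complex with assembled features and contact labels."""
    for _ in range(max_retries):
        n_ag = int(rng.integers(*spec.antigen_residues, endpoint=True))
        n_ab = int(rng.integers(*spec.antibody_residues, endpoint=True))
        antigen = _build_chain(n_ag, spec, "A", rng)
        antibody = _build_chain(n_ab, spec, "H", rng)
        placed = _place_antibody(antigen, antibody, spec, rng)
        if placed is None:
            continue
        antibody, labels = placed
        complex = ComplexStructure(antigen, antibody, complex_id)
        epitope_mask = labels.labels.astype(bool)
        ag_res = _planted_residue_features(antigen, epitope_mask, spec, rng)
        ab_res = _planted_residue_features(
            antibody, np.zeros(antibody.n_residues, bool), spec, rng)
        return ComplexSample(
            complex_id=complex_id,
            antigen_atoms=compute_atom_features(antigen),
            antigen_starts=antigen.residue_starts,
            antigen_residues=ag_res,
            antibody_atoms=compute_atom_features(antibody),
            antibody_starts=antibody.residue_starts,
            antibody_residues=ab_res,
            labels=labels,
            structure=complex,
        )
    raise RuntimeError(
        "could not place the antibody at the requested contact fraction; "
        "widen contact_tolerance or enlarge the chains")


def generate_dataset(spec: SyntheticSpec,
                     rng: np.random.Generator | int | None = None
                     ) -> list[ComplexSample]:
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.rng_seed if rng is None else rng)
    return [generate_complex(spec, rng, complex_id=f"synth_{i:04d}")
            for i in range(spec.n_complexes)]


def write_fixture_pdb(complex: ComplexStructure, path: str | Path) -> Path:
    """Write a minimal, valid PDB file readable by ``parse_pdb``."""
    import gemmi

    st = gemmi.Structure()
    st.name = complex.complex_id
    model = gemmi.Model("1")
    for chain_struct in (complex.antigen, complex.antibody):
        res_of = chain_struct.atom_residue_index
        current: dict[str, gemmi.Chain] = {}
        for j in range(chain_struct.n_residues):
            cid = str(chain_struct.chain_ids[j])
            if cid not in current:
                current[cid] = gemmi.Chain(cid)
            res = gemmi.Residue()
            res.name = str(chain_struct.residue_names[j])
            res.seqid = gemmi.SeqId(j + 1, " ")
            sl = chain_struct.residue_slice(j)
            for i in range(sl.start, sl.stop):
                atom = gemmi.Atom()
                atom.name = str(chain_struct.atom_names[i])
                atom.element = gemmi.Element(str(chain_struct.elements[i]))
                x, y, z = chain_struct.coords[i]
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            current[cid].add_residue(res)
        for chain in current.values():
            model.add_chain(chain)
    st.add_model(model)
    path = Path(path)
    st.write_pdb(str(path))
    return path
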