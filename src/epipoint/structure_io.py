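"""Parsing, cleaning, and indexing of antibody-antigen complex structures.

A complex is represented as two :class:`ChainStructure` objects (antigen and
antibody); each stores a flat, ordered atom list plus the list of start
indices marking the first atom of every residue, so the atom-to-residue
mapping is a total surjective function. Multi-chain antigens or antibodies
are concatenated in file order into a single ordered list with one
continuous 0-based residue index.

Epitope residues are antigen residues with any heavy atom within 4.5 A of
any antibody heavy atom; interface residues use an 8 A all-atom cutoff.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by 3-letter code. This ordering
#: fixes the column order of every one-hot / PSSM / composition feature block.
STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA_INDEX = {name: i for i, name in enumerate(STANDARD_AA)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

ALLOWED_ELEMENTS = ("C", "N", "O", "S", "H")

# solvent / ion / cryo-additive names removed silently during cleaning;
# any other non-standard residue (e.g. MSE) is dropped with a warning so
# users can pre-convert if they care about it.
_SOLVENT_NAMES = {
    "HOH", "WAT", "DOD", "H2O", "NA", "CL", "K", "MG", "CA", "ZN", "MN",
    "FE", "FE2", "CU", "NI", "CO", "CD", "HG", "SO4", "PO4", "GOL", "EDO",
    "PEG", "ACT", "DMS", "NAG", "NO3", "IOD", "BR",
}

DEFAULT_EPITOPE_CUTOFF = 4.5   # A, heavy-atom rule
DEFAULT_INTERFACE_CUTOFF = 8.0  # A, all-atom rule


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its chain/residue identity."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    is_heavy: bool


@dataclass
class ChainStructure:
    """An ordered atom list with residue boundaries (one logical chain).

    ``residue_starts[j]`` is the index of the first atom of residue ``j``;
    atoms of a residue are contiguous, so residue ``j`` owns atoms
    ``residue_starts[j] : residue_starts[j+1]``.
    """

    coords: np.ndarray                  # (N, 3) float, Angstrom
    elements: np.ndarray                # (N,) unicode
    atom_names: np.ndarray              # (N,) unicode
    residue_starts: np.ndarray          # (R,) int
    residue_names: np.ndarray           # (R,) unicode 3-letter codes
    chain_ids: np.ndarray               # (R,) original author chain id
    residue_labels: np.ndarray = field(default=None)  # (R,) author seq id + icode

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype="U2")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.residue_starts = np.asarray(self.residue_starts, dtype=np.int64)
        self.residue_names = np.asarray(self.residue_names, dtype="U3")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        if self.residue_labels is None:
            self.residue_labels = np.array(
                [str(i) for i in range(len(self.residue_starts))], dtype="U8")
        self._validate()

    def _validate(self) -> None:
        if self.n_residues == 0:
            raise ValueError("chain has no residues")
        rs = self.residue_starts
        if rs[0] != 0 or np.any(np.diff(rs) < 1):
            raise ValueError("residue_starts must start at 0 and be strictly increasing")
        if rs[-1] >= self.n_atoms:
            raise ValueError("residue_starts exceed atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.residue_starts.shape[0]

    @property
    def is_heavy(self) -> np.ndarray:
        return ~np.isin(self.elements, ("H", "D"))

    @property
    def atom_residue_index(self) -> np.ndarray:
        """(N,) residue index of every atom (the atom-to-residue mapping)."""
        counts = np.diff(np.append(self.residue_starts, self.n_atoms))
        return np.repeat(np.arange(self.n_residues), counts)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(name, "X") for name in self.residue_names)

    def residue_slice(self, j: int) -> slice:
        lo = self.residue_starts[j]
        hi = self.residue_starts[j + 1] if j + 1 < self.n_residues else self.n_atoms
        return slice(int(lo), int(hi))

    def atom_records(self) -> Iterator[AtomRecord]:
        res_of = self.atom_residue_index
        heavy = self.is_heavy
        for i in range(self.n_atoms):
            j = int(res_of[i])
            yield AtomRecord(
                chain_id=str(self.chain_ids[j]),
                residue_index=j,
                residue_name=str(self.residue_names[j]),
                atom_name=str(self.atom_names[i]),
                element=str(self.elements[i]),
                coords=self.coords[i],
                is_heavy=bool(heavy[i]),
            )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "ChainStructure":
        """Return a rigidly transformed copy (testing / augmentation helper)."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation)
        return ChainStructure(coords, self.elements.copy(), self.atom_names.copy(),
                              self.residue_starts.copy(), self.residue_names.copy(),
                              self.chain_ids.copy(), self.residue_labels.copy())


@dataclass
class ComplexStructure:
    antigen: ChainStructure
    antibody: ChainStructure
    complex_id: str = "complex"


@dataclass
class EpitopeLabels:
    """Binary per-antigen-residue labels; 1 marks an epitope residue."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)


# --------------------------------------------------------------------- parsing

def _resolve_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Keep the highest-occupancy alternative location; ties prefer altloc 'A'."""
    if len(atoms) == 1:
        return atoms[0]
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc != "A", a.altloc))[0]


def _chains_to_structure(chains: list[gemmi.Chain]) -> ChainStructure:
    coords, elements, atom_names = [], [], []
    starts, res_names, chain_ids, res_labels = [], [], [], []
    n = 0
    for chain in chains:
        for residue in chain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            picked = [_resolve_altloc(group) for group in by_name.values()]
            if not picked:
                continue
            starts.append(n)
            res_names.append(residue.name)
            chain_ids.append(chain.name)
            seqid = residue.seqid
            res_labels.append(f"{seqid.num}{seqid.icode}".strip())
            for atom in picked:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elem = atom.element.name.upper()
                elements.append("H" if elem == "D" else elem)
                atom_names.append(atom.name)
                n += 1
    if n == 0:
        raise ValueError("no atoms found in the selected chains")
    return ChainStructure(np.array(coords), np.array(elements),
                          np.array(atom_names), np.array(starts),
                          np.array(res_names), np.array(chain_ids),
                          np.array(res_labels, dtype="U8"))


def parse_pdb(path: str | Path, antigen_chains: Iterable[str],
              antibody_chains: Iterable[str], clean: bool = True,
              complex_id: str | None = None) -> ComplexStructure:
    """Parse a PDB file into an antigen/antibody :class:`ComplexStructure`.

    Chains are taken in file order; alternative locations are resolved to
    the highest-occupancy conformer (ties prefer altloc 'A'); insertion
    codes are preserved through file ordering. With ``clean=True`` (the
    default) solvent, ions, ligands, and non-standard residues are removed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    antigen_chains = list(antigen_chains)
    antibody_chains = list(antibody_chains)
    st = gemmi.read_structure(str(path), merge_chain_parts=True)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    available = {c.name: c for c in model}

    def select(wanted: list[str], role: str) -> list[gemmi.Chain]:
        missing = [c for c in wanted if c not in available]
        if missing:
            raise KeyError(
                f"{role} chain(s) {missing} not found in {path.name}; "
                f"available chains: {sorted(available)}")
        # preserve file order, not request order
        return [c for c in model if c.name in set(wanted)]

    cs = ComplexStructure(
        antigen=_chains_to_structure(select(antigen_chains, "antigen")),
        antibody=_chains_to_structure(select(antibody_chains, "antibody")),
        complex_id=complex_id or path.stem,
    )
    return clean_structure(cs) if clean else cs


def _clean_chain(chain: ChainStructure, role: str) -> ChainStructure:
    keep = np.array([name in AA_INDEX for name in chain.residue_names])
    dropped = chain.residue_names[~keep]
    noteworthy = [n for n in dropped if n not in _SOLVENT_NAMES]
    if noteworthy:
        logger.warning("dropping %d non-standard residue(s) from %s chain: %s",
                       len(noteworthy), role, sorted(set(noteworthy)))
    if not keep.any():
        raise ValueError(f"{role} chain empty after cleaning")
    res_of = chain.atom_residue_index
    atom_keep = keep[res_of]
    coords = chain.coords[atom_keep]
    elements = chain.elements[atom_keep]
    atom_names = chain.atom_names[atom_keep]
    counts = np.diff(np.append(chain.residue_starts, chain.n_atoms))[keep]
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    cleaned = ChainStructure(coords, elements, atom_names, starts,
                             chain.residue_names[keep], chain.chain_ids[keep],
                             chain.residue_labels[keep])
    bad = ~np.isin(cleaned.elements, ALLOWED_ELEMENTS)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"unexpected element {cleaned.elements[i]!r} on atom "
            f"{cleaned.atom_names[i]!r} in a standard residue of the {role} chain")
    return cleaned


def clean_structure(raw: ComplexStructure) -> ComplexStructure:
    """Remove solvent, ions, ligands and non-standard residues."""
    return ComplexStructure(
        antigen=_clean_chain(raw.antigen, "antigen"),
        antibody=_clean_chain(raw.antibody, "antibody"),
        complex_id=raw.complex_id,
    )


# -------------------------------------------------------------------- labelling

def _residues_within(query: ChainStructure, target: ChainStructure,
                     cutoff: float, heavy_only: bool) -> np.ndarray:
    """Boolean mask over ``query`` residues with any (heavy) atom within
    ``cutoff`` of any (heavy) atom of ``target``. Inclusive boundary."""
    q_mask = query.is_heavy if heavy_only else np.ones(query.n_atoms, bool)
    t_mask = target.is_heavy if heavy_only else np.ones(target.n_atoms, bool)
    q_coords = query.coords[q_mask]
    t_coords = target.coords[t_mask]
    out = np.zeros(query.n_residues, dtype=bool)
    if len(q_coords) == 0 or len(t_coords) == 0:
        return out
    tree = cKDTree(t_coords)
    # query_ball_point uses an inclusive (<=) radius
    hits = tree.query_ball_point(q_coords, r=cutoff, return_length=True) > 0
    res_of = query.atom_residue_index[q_mask]
    out[np.unique(res_of[hits])] = True
    return out


def label_epitopes(complex: ComplexStructure,
                   cutoff: float = DEFAULT_EPITOPE_CUTOFF) -> EpitopeLabels:
    """Label antigen residues with a heavy atom <= ``cutoff`` A from any
    antibody heavy atom (hydrogens excluded on both sides)."""
    ag, ab = complex.antigen, complex.antibody
    if not ag.is_heavy.any() or not ab.is_heavy.any():
        raise ValueError("both chains need at least one heavy atom")
    mask = _residues_within(ag, ab, cutoff, heavy_only=True)
    return EpitopeLabels(mask.astype(np.int64))


def interface_residues(complex: ComplexStructure,
                       cutoff: float = DEFAULT_INTERFACE_CUTOFF
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric all-atom interface sets at ``cutoff`` A (hydrogens included
    when present). Returns sorted residue index arrays (antigen, antibody)."""
    ag_mask = _residues_within(complex.antigen, complex.antibody, cutoff, False)
    ab_mask = _residues_within(complex.antibody, complex.antigen, cutoff, False)
    return np.flatnonzero(ag_mask), np.flatnonzero(ab_mask)


# ------------------------------------------------------------ dataset directory

def _write_chain_tables(outdir: Path, prefix: str, chain: ChainStructure) -> None:
    import pandas as pd

    res_of = chain.atom_residue_index
    atoms = pd.DataFrame({
        "chain_id": chain.chain_ids[res_of],
        "residue_index": res_of,
        "residue_name": chain.residue_names[res_of],
        "atom_name": chain.atom_names,
        "element": chain.elements,
        "x": chain.coords[:, 0], "y": chain.coords[:, 1], "z": chain.coords[:, 2],
    })
    atoms.to_csv(outdir / f"{prefix}_atoms.tsv", sep="\t", index=False,
                 float_format="%.3f")
    mapping = pd.DataFrame({
        "residue_index": np.arange(chain.n_residues),
        "residue_name": chain.residue_names,
        "chain_id": chain.chain_ids,
        "author_label": chain.residue_labels,
        "atom_start": chain.residue_starts,
    })
    mapping.to_csv(outdir / f"{prefix}_residues.tsv", sep="\t", index=False)


def save_complex_dir(outdir: str | Path, complex: ComplexStructure,
                     labels: EpitopeLabels | None = None,
                     antigen_features=None, antibody_features=None,
                     metadata: dict | None = None) -> Path:
    """Serialize one complex as a directory of plain columnar text tables.

    ``*_features`` are ``(AtomFeatureMatrix, ResidueFeatureMatrix,
    PLMEmbeddingMatrix | None)`` tuples from :mod:`epipoint.features`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_chain_tables(outdir, "antigen", complex.antigen)
    _write_chain_tables(outdir, "antibody", complex.antibody)
    if labels is not None:
        np.savetxt(outdir / "labels.tsv", labels.labels, fmt="%d")
    for prefix, feats in (("antigen", antigen_features),
                          ("antibody", antibody_features)):
        if feats is None:
            continue
        atom_fm, res_fm, plm = feats
        np.savetxt(outdir / f"{prefix}_atom_features.tsv",
                   atom_fm.as_matrix(), fmt="%.6g", delimiter="\t")
        np.savetxt(outdir / f"{prefix}_residue_features.tsv",
                   res_fm.as_matrix(), fmt="%.6g", delimiter="\t")
        if plm is not None:
            np.savetxt(outdir / f"{prefix}_plm.tsv", plm.values,
                       fmt="%.6g", delimiter="\t")
    meta = {"complex_id": complex.complex_id,
            "n_antigen_residues": int(complex.antigen.n_residues),
            "n_antibody_residues": int(complex.antibody.n_residues)}
    meta.update(metadata or {})
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    return outdir


def load_chain_tables(indir: str | Path, prefix: str) -> ChainStructure:
    import pandas as pd

    indir = Path(indir)
    atoms = pd.read_csv(indir / f"{prefix}_atoms.tsv", sep="\t")
    mapping = pd.read_csv(indir / f"{prefix}_residues.tsv", sep="\t")
    return ChainStructure(
        coords=atoms[["x", "y", "z"]].to_numpy(),
        elements=atoms["element"].to_numpy(dtype="U2"),
        atom_names=atoms["atom_name"].to_numpy(dtype="U6"),
        residue_starts=mapping["atom_start"].to_numpy(),
        residue_names=mapping["residue_name"].to_numpy(dtype="U3"),
        chain_ids=mapping["chain_id"].to_numpy(dtype="U4"),
        residue_labels=mapping["author_label"].to_numpy(dtype="U8"),
    )


def load_complex_dir(indir: str | Path) -> tuple[ComplexStructure, EpitopeLabels | None]:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    cs = ComplexStructure(
        antigen=load_chain_tables(indir, "antigen"),
        antibody=load_chain_tables(indir, "antibody"),
        complex_id=meta.get("complex_id", indir.name),
    )
    labels = None
    labels_path = indir / "labels.tsv"
    if labels_path.exists():
        labels = EpitopeLabels(np.loadtxt(labels_path, dtype=np.int64, ndmin=1))
    return cs, labels
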