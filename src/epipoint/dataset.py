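"""In-memory training samples and their plain-text serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import (AtomFeatureMatrix, FeatureOptions, PLMEmbeddingMatrix,
                       ResidueFeatureMatrix, assemble_features)
from .structure_io import (ComplexStructure, EpitopeLabels, label_epitopes,
                           load_complex_dir, save_complex_dir)

__all__ = ["ComplexSample", "build_sample", "save_sample", "load_sample",
           "save_dataset", "load_dataset"]


@dataclass
class ComplexSample:
    """One antigen-antibody complex with assembled features and labels."""

    complex_id: str
    antigen_atoms: AtomFeatureMatrix
    antigen_starts: np.ndarray
    antigen_residues: ResidueFeatureMatrix
    antibody_atoms: AtomFeatureMatrix
    antibody_starts: np.ndarray
    antibody_residues: ResidueFeatureMatrix
    labels: EpitopeLabels
    antigen_plm: np.ndarray | None = None
    antibody_plm: np.ndarray | None = None
    structure: ComplexStructure | None = None

    @property
    def n_antigen_residues(self) -> int:
        return self.antigen_residues.n_residues


def build_sample(complex: ComplexStructure,
                 options: FeatureOptions | None = None,
                 labels: EpitopeLabels | None = None) -> ComplexSample:
    """Assemble features (and 4.5 A contact labels, if not given) for a
    cleaned complex."""
    feats = assemble_features(complex, options)
    ag_atoms, ag_res, ag_plm = feats["antigen"]
    ab_atoms, ab_res, ab_plm = feats["antibody"]
    if labels is None:
        labels = label_epitopes(complex)
    return ComplexSample(
        complex_id=complex.complex_id,
        antigen_atoms=ag_atoms, antigen_starts=complex.antigen.residue_starts,
        antigen_residues=ag_res,
        antibody_atoms=ab_atoms, antibody_starts=complex.antibody.residue_starts,
        antibody_residues=ab_res,
        labels=labels,
        antigen_plm=None if ag_plm is None else ag_plm.values,
        antibody_plm=None if ab_plm is None else ab_plm.values,
        structure=complex,
    )


def save_sample(outdir: str | Path, sample: ComplexSample,
                metadata: dict | None = None) -> Path:
    if sample.structure is None:
        raise ValueError("sample has no structure attached; cannot serialize")
    ag_plm = (PLMEmbeddingMatrix(sample.antigen_plm)
              if sample.antigen_plm is not None else None)
    ab_plm = (PLMEmbeddingMatrix(sample.antibody_plm)
              if sample.antibody_plm is not None else None)
    return save_complex_dir(
        outdir, sample.structure, labels=sample.labels,
        antigen_features=(sample.antigen_atoms, sample.antigen_residues, ag_plm),
        antibody_features=(sample.antibody_atoms, sample.antibody_residues, ab_plm),
        metadata=metadata)


def _load_chain_features(indir: Path, prefix: str):
    atom_m = np.loadtxt(indir / f"{prefix}_atom_features.tsv", ndmin=2)
    atoms = AtomFeatureMatrix(atom_m[:, :3], atom_m[:, 3:8], atom_m[:, 8:11])
    res = ResidueFeatureMatrix.from_matrix(
        np.loadtxt(indir / f"{prefix}_residue_features.tsv", ndmin=2))
    plm_path = indir / f"{prefix}_plm.tsv"
    plm = np.loadtxt(plm_path, ndmin=2) if plm_path.exists() else None
    return atoms, res, plm


def load_sample(indir: str | Path) -> ComplexSample:
    indir = Path(indir)
    structure, labels = load_complex_dir(indir)
    if labels is None:
        raise ValueError(f"{indir}: no labels.tsv")
    ag_atoms, ag_res, ag_plm = _load_chain_features(indir, "antigen")
    ab_atoms, ab_res, ab_plm = _load_chain_features(indir, "antibody")
    return ComplexSample(
        complex_id=structure.complex_id,
        antigen_atoms=ag_atoms, antigen_starts=structure.antigen.residue_starts,
        antigen_residues=ag_res,
        antibody_atoms=ab_atoms, antibody_starts=structure.antibody.residue_starts,
        antibody_residues=ab_res, labels=labels,
        antigen_plm=ag_plm, antibody_plm=ab_plm, structure=structure)


def save_dataset(outdir: str | Path, samples: list[ComplexSample],
                 splits: dict[str, list[str]] | None = None,
                 metadata: dict | None = None) -> Path:
    """One sub-directory per complex plus a manifest listing splits."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample in samples:
        save_sample(outdir / sample.complex_id, sample)
    manifest = {"complexes": [s.complex_id for s in samples],
                "splits": splits or {"train": [s.complex_id for s in samples]},
                "metadata": metadata or {}}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def load_dataset(indir: str | Path, split: str | None = None
                 ) -> list[ComplexSample]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    if split is None:
        ids = manifest["complexes"]
    else:
        if split not in manifest["splits"]:
            raise KeyError(f"split {split!r} not in manifest "
                           f"(has {sorted(manifest['splits'])})")
        ids = manifest["splits"][split]
    return [load_sample(indir / cid) for cid in ids]
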