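"""Atomic and residue feature computation."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from epipoint.features import (AtomFeatureMatrix, FeatureOptions,
                               ResidueFeatureMatrix, assemble_features,
                               compute_atom_type_onehot,
                               compute_neighbor_composition,
                               compute_residue_onehot,
                               compute_solvent_accessibility,
                               compute_surface_normals, load_plm_table,
                               load_pssm, parse_psiblast_pssm, pseudo_pssm,
                               squash_pssm)
from epipoint.structure_io import AA_INDEX, STANDARD_AA, ChainStructure


def make_chain(coords, elements, atom_names, starts, res_names):
    return ChainStructure(np.asarray(coords, float), np.asarray(elements),
                          np.asarray(atom_names), np.asarray(starts),
                          np.asarray(res_names),
                          np.full(len(starts), "A"))


def poly_chain(res_name, n_res, rng, atoms_per_res=5):
    coords, elements, names, starts = [], [], [], []
    for j in range(n_res):
        starts.append(j * atoms_per_res)
        center = np.array([j * 3.8, 0.0, 0.0])
        coords.append(center)
        elements.append("C")
        names.append("CA")
        for k in range(atoms_per_res - 1):
            coords.append(center + rng.normal(0, 0.8, 3))
            elements.append("C")
            names.append(f"C{k + 1}")
    return make_chain(coords, elements, names, starts, [res_name] * n_res)


# ------------------------------------------------------------------ atom types

def test_atom_onehot_counts_match_elements(small_sample):
    chain = small_sample.structure.antigen
    onehot = compute_atom_type_onehot(chain)
    for col, elem in enumerate(("C", "N", "O", "S", "H")):
        assert onehot[:, col].sum() == np.sum(chain.elements == elem)
    assert np.allclose(onehot.sum(axis=1), 1.0)


def test_glycine_backbone_composition():
    chain = make_chain([[0, 0, 0], [1.5, 0, 0], [2.1, 1.4, 0], [1.4, 2.4, 0]],
                       ["N", "C", "C", "O"], ["N", "CA", "C", "O"], [0], ["GLY"])
    onehot = compute_atom_type_onehot(chain)
    assert list(onehot.sum(axis=0)) == [2, 1, 1, 0, 0]


def test_unknown_element_raises_naming_atom():
    chain = make_chain([[0, 0, 0]], ["FE"], ["FE1"], [0], ["GLY"])
    with pytest.raises(ValueError, match="FE1"):
        compute_atom_type_onehot(chain)


# -------------------------------------------------------------- surface normals

def test_sphere_normals_are_radial():
    rng = np.random.default_rng(0)
    n = 400
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= 10.0
    chain = make_chain(pts, ["C"] * n, [f"C{i}" for i in range(n)],
                       np.arange(n), ["GLY"] * n)
    normals = compute_surface_normals(chain, k_neighbors=16)
    radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    cosang = np.abs(np.sum(normals * radial, axis=1))
    within_15deg = np.mean(cosang >= np.cos(np.radians(15.0)))
    assert within_15deg >= 0.95
    assert np.allclose(np.linalg.norm(normals, axis=1), 1.0, atol=1e-6)
    # outward orientation: positive projection on the radial direction
    assert np.mean(np.sum(normals * radial, axis=1) > 0) >= 0.95


def test_collinear_neighbourhood_falls_back_to_centroid_direction():
    n = 20
    pts = np.stack([np.linspace(0, 19, n), np.zeros(n), np.zeros(n)], axis=1)
    chain = make_chain(pts, ["C"] * n, [f"C{i}" for i in range(n)],
                       np.arange(n), ["GLY"] * n)
    normals = compute_surface_normals(chain, k_neighbors=4)
    # centroid is on the line; the last atom's fallback points along +x
    assert np.allclose(normals[-1], [1.0, 0.0, 0.0])


def test_normals_rotate_covariantly(small_sample):
    chain = small_sample.structure.antigen
    rot = special_ortho_group.rvs(3, random_state=np.random.default_rng(5))
    normals = compute_surface_normals(chain, 16)
    rotated_chain = chain.transformed(rotation=rot)
    normals_rot = compute_surface_normals(rotated_chain, 16)
    assert np.allclose(normals_rot, normals @ rot.T, atol=1e-5)


# ------------------------------------------------------------------ residue ids

def test_residue_onehot_round_trips_sequence(small_sample):
    chain = small_sample.structure.antigen
    onehot = compute_residue_onehot(chain)
    recovered = [STANDARD_AA[i] for i in onehot.argmax(axis=1)]
    assert recovered == list(chain.residue_names)


def test_poly_gly_onehot_column_sum(rng):
    chain = poly_chain("GLY", 10, rng)
    onehot = compute_residue_onehot(chain)
    assert onehot[:, AA_INDEX["GLY"]].sum() == 10


# ------------------------------------------------------------------------ PSSM

PSSM_HEADER = ("\nLast position-specific scoring matrix computed\n"
               "            A   R   N   D   C   Q   E   G   H   I   L   K   M"
               "   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G"
               "   H   I   L   K   M   F   P   S   T   W   Y   V\n")


def write_pssm(path, sequence, scores):
    rows = []
    for i, (letter, row) in enumerate(zip(sequence, scores), start=1):
        logodds = "  ".join(f"{int(v):3d}" for v in row)
        freqs = "  ".join("0" for _ in range(20))
        rows.append(f"{i:5d} {letter}  {logodds}  {freqs}  1.0 1.0")
    path.write_text(PSSM_HEADER + "\n".join(rows) + "\n")


def test_pssm_parser_reads_hand_written_values(tmp_path):
    scores = [[1] * 20, [-2] * 20, list(range(-9, 11))]
    path = tmp_path / "test.pssm"
    write_pssm(path, "GAV", scores)
    seq, raw = parse_psiblast_pssm(path)
    assert seq == "GAV"
    # PSI-BLAST column order equals the package's alphabetical 3-letter order
    assert np.array_equal(raw, np.array(scores, dtype=float))


def test_load_pssm_squashes_and_checks_sequence(tmp_path, rng):
    chain = poly_chain("GLY", 3, rng)
    path = tmp_path / "zero.pssm"
    write_pssm(path, "GGG", [[0] * 20] * 3)
    values = load_pssm(path, chain)
    assert np.allclose(values, 0.5)  # logistic(0) = 1/2


def test_pssm_sequence_mismatch_reports_position(tmp_path, rng):
    chain = poly_chain("GLY", 3, rng)
    path = tmp_path / "bad.pssm"
    write_pssm(path, "GGA", [[0] * 20] * 3)
    with pytest.raises(ValueError, match="position 3"):
        load_pssm(path, chain)


def test_pseudo_pssm_is_squashed_blosum_row(rng):
    from Bio.Align import substitution_matrices

    chain = poly_chain("ALA", 4, rng)
    values = pseudo_pssm(chain)
    blosum = substitution_matrices.load("BLOSUM62")
    from epipoint.structure_io import THREE_TO_ONE
    expected = squash_pssm(np.array(
        [blosum["A", THREE_TO_ONE[a]] for a in STANDARD_AA]))
    assert np.allclose(values, expected[None, :].repeat(4, axis=0))
    assert np.array_equal(values[0], values[1])  # identical residues, identical rows


# -------------------------------------------------------------- solvent access

def test_isolated_residue_is_fully_exposed(rng):
    chain = poly_chain("ALA", 1, rng, atoms_per_res=5)
    acc = compute_solvent_accessibility(chain)
    assert acc.shape == (1, 2)
    assert acc[0, 1] > 0.8  # nothing occludes a lone residue


def test_burial_reduces_accessibility(rng):
    lone = poly_chain("ALA", 1, rng, atoms_per_res=5)
    acc_lone = compute_solvent_accessibility(lone)
    # surround the same residue with a dense shell of occluding atoms
    shell_pts = rng.normal(size=(300, 3))
    shell_pts = 4.0 * shell_pts / np.linalg.norm(shell_pts, axis=1, keepdims=True)
    coords = np.vstack([lone.coords, shell_pts])
    elements = np.concatenate([lone.elements, ["C"] * 300])
    names = np.concatenate([lone.atom_names,
                            [f"X{i}" for i in range(300)]])
    starts = np.array([0, lone.n_atoms])
    chain = make_chain(coords, elements, names, starts, ["ALA", "GLY"])
    acc_buried = compute_solvent_accessibility(chain)
    assert acc_buried[0, 1] < acc_lone[0, 1]


def test_asa_converges_with_sample_count(small_sample):
    chain = small_sample.structure.antigen
    a1 = compute_solvent_accessibility(chain, point_number=500)[:, 0]
    a2 = compute_solvent_accessibility(chain, point_number=1000)[:, 0]
    total1, total2 = a1.sum(), a2.sum()
    assert abs(total1 - total2) / total2 < 0.02


# --------------------------------------------------------- neighbour composition

def test_poly_gly_composition_is_gly_indicator(rng):
    chain = poly_chain("GLY", 8, rng)
    comp = compute_neighbor_composition(chain, radius=10.0)
    expected = np.zeros(20)
    expected[AA_INDEX["GLY"]] = 1.0
    assert np.allclose(comp, expected[None, :])


def test_composition_matches_brute_force(small_sample):
    chain = small_sample.structure.antigen
    comp = compute_neighbor_composition(chain, radius=10.0)
    assert np.allclose(comp.sum(axis=1), 1.0)
    ca = chain.coords[chain.residue_starts]  # generator puts CA first
    aa_idx = np.array([AA_INDEX[a] for a in chain.residue_names])
    for j in range(chain.n_residues):
        d = np.linalg.norm(ca - ca[j], axis=1)
        nbrs = aa_idx[(d <= 10.0) & (np.arange(len(ca)) != j)]
        expected = np.bincount(nbrs, minlength=20) / len(nbrs)
        assert np.allclose(comp[j], expected)


# -------------------------------------------------------------------- assembly

def test_assembled_widths_are_11_and_62(small_sample):
    feats = assemble_features(small_sample.structure)
    for role in ("antigen", "antibody"):
        atoms, residues, plm = feats[role]
        assert atoms.as_matrix().shape[1] == 11
        assert residues.as_matrix().shape[1] == 62
        assert plm is None


def test_plm_row_count_mismatch_raises(small_sample):
    chain = small_sample.structure.antigen
    bad = np.zeros((chain.n_residues + 1, 480))
    with pytest.raises(ValueError, match="rows"):
        load_plm_table(bad, chain, 480)


def test_plm_block_attached_when_provided(small_sample):
    cs = small_sample.structure
    opts = FeatureOptions(
        antigen_plm=np.zeros((cs.antigen.n_residues, 480)),
        antibody_plm=np.zeros((cs.antibody.n_residues, 512)))
    feats = assemble_features(cs, opts)
    assert feats["antigen"][2].dim == 480
    assert feats["antibody"][2].dim == 512


def test_residue_feature_matrix_rejects_wrong_width():
    with pytest.raises(ValueError):
        ResidueFeatureMatrix.from_matrix(np.zeros((3, 61)))
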