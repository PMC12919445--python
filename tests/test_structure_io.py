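"""Parsing, cleaning, atom-residue mapping, and contact labelling."""

import logging

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import special_ortho_group

from epipoint.structure_io import (ChainStructure, ComplexStructure,
                                   clean_structure, interface_residues,
                                   label_epitopes, parse_pdb)
from epipoint.synthetic import (SyntheticSpec, generate_complex,
                                write_fixture_pdb)


def _atom_line(serial, name, resname, chain, resseq, xyz, elem,
               record="ATOM", altloc=" ", occ=1.0):
    x, y, z = xyz
    return (f"{record:<6s}{serial:5d} {name:<4s}{altloc}{resname:>3s} "
            f"{chain}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {elem:>2s}")


@pytest.fixture
def fixture_pdb(tmp_path):
    """GLY + ALA antigen (chain A), one-GLY antibody (chain H), plus water,
    zinc, a ligand, and an MSE residue that cleaning must remove."""
    lines = [
        _atom_line(1, " N", "GLY", "A", 1, (0.0, 0.0, 0.0), "N"),
        _atom_line(2, " CA", "GLY", "A", 1, (1.46, 0.0, 0.0), "C"),
        _atom_line(3, " C", "GLY", "A", 1, (2.0, 1.4, 0.0), "C"),
        _atom_line(4, " O", "GLY", "A", 1, (1.3, 2.4, 0.0), "O"),
        _atom_line(5, " N", "ALA", "A", 2, (3.3, 1.5, 0.0), "N"),
        _atom_line(6, " CA", "ALA", "A", 2, (4.0, 2.7, 0.3), "C"),
        _atom_line(7, " C", "ALA", "A", 2, (5.5, 2.5, 0.3), "C"),
        _atom_line(8, " O", "ALA", "A", 2, (6.0, 1.4, 0.2), "O"),
        # two alternative CB conformers: B has higher occupancy and must win
        _atom_line(9, " CB", "ALA", "A", 2, (3.6, 3.6, 1.4), "C",
                   altloc="A", occ=0.4),
        _atom_line(10, " CB", "ALA", "A", 2, (3.7, 3.7, 1.5), "C",
                    altloc="B", occ=0.6),
        _atom_line(11, " N", "MSE", "A", 3, (6.2, 3.6, 0.5), "N"),
        _atom_line(12, "SE", "MSE", "A", 3, (7.0, 4.0, 1.0), "SE"),
        _atom_line(13, " N", "GLY", "H", 1, (3.0, 6.0, 0.0), "N"),
        _atom_line(14, " CA", "GLY", "H", 1, (4.4, 6.2, 0.0), "C"),
        _atom_line(15, " C", "GLY", "H", 1, (5.0, 7.5, 0.0), "C"),
        _atom_line(16, " O", "GLY", "H", 1, (4.4, 8.6, 0.0), "O"),
        _atom_line(17, " O", "HOH", "A", 101, (9.0, 9.0, 9.0), "O",
                   record="HETATM"),
        _atom_line(18, "ZN", "ZN", "A", 102, (10.0, 10.0, 10.0), "ZN",
                   record="HETATM"),
        _atom_line(19, " C1", "LIG", "A", 103, (11.0, 11.0, 11.0), "C",
                   record="HETATM"),
        "END",
    ]
    path = tmp_path / "fixture.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def test_parse_cleans_and_indexes_residues(fixture_pdb, caplog):
    with caplog.at_level(logging.WARNING):
        cs = parse_pdb(fixture_pdb, ["A"], ["H"])
    ag = cs.antigen
    # MSE, water, zinc, ligand all gone; GLY(4 atoms) then ALA(5 atoms)
    assert ag.n_residues == 2
    assert list(ag.residue_starts) == [0, 4]
    assert ag.n_atoms == 9
    assert list(ag.residue_names) == ["GLY", "ALA"]
    assert cs.antibody.n_residues == 1
    assert "MSE" in caplog.text


def test_altloc_resolution_keeps_highest_occupancy(fixture_pdb):
    cs = parse_pdb(fixture_pdb, ["A"], ["H"])
    cb = cs.antigen.coords[list(cs.antigen.atom_names).index("CB")]
    assert np.allclose(cb, (3.7, 3.7, 1.5), atol=1e-3)  # the 0.6-occ conformer


def test_missing_chain_error_names_the_chain(fixture_pdb):
    with pytest.raises(KeyError, match="X"):
        parse_pdb(fixture_pdb, ["X"], ["H"])


def test_clean_structure_is_identity_on_standard_residues(fixture_pdb):
    cs = parse_pdb(fixture_pdb, ["A"], ["H"])
    again = clean_structure(cs)
    assert np.array_equal(again.antigen.coords, cs.antigen.coords)
    assert np.array_equal(again.antigen.residue_starts, cs.antigen.residue_starts)


def test_atom_residue_mapping_is_total_and_surjective(small_sample):
    chain = small_sample.structure.antigen
    res_of = chain.atom_residue_index
    assert len(res_of) == chain.n_atoms
    assert set(res_of) == set(range(chain.n_residues))  # every residue owns >= 1 atom


def _single_atom_complex(distance):
    def chain(x, cid):
        return ChainStructure(np.array([[x, 0.0, 0.0]]), np.array(["C"]),
                              np.array(["CA"]), np.array([0]),
                              np.array(["GLY"]), np.array([cid]))
    return ComplexStructure(chain(0.0, "A"), chain(distance, "H"))


def test_epitope_boundary_is_inclusive_at_cutoff():
    assert label_epitopes(_single_atom_complex(4.5)).labels[0] == 1
    assert label_epitopes(_single_atom_complex(4.5001)).labels[0] == 0


def test_distant_antibody_gives_all_zero_labels(small_sample):
    cs = small_sample.structure
    far = ComplexStructure(cs.antigen,
                           cs.antibody.transformed(translation=[1000.0, 0, 0]))
    assert label_epitopes(far).labels.sum() == 0


def brute_force_labels(cs, cutoff=4.5):
    ag, ab = cs.antigen, cs.antibody
    d = cdist(ag.coords[ag.is_heavy], ab.coords[ab.is_heavy])
    res_of = ag.atom_residue_index[ag.is_heavy]
    labels = np.zeros(ag.n_residues, dtype=np.int64)
    for j in range(ag.n_residues):
        rows = d[res_of == j]
        if rows.size and rows.min() <= cutoff:
            labels[j] = 1
    return labels


def test_labels_match_brute_force_scan_on_random_complexes(small_spec):
    rng = np.random.default_rng(42)
    for i in range(10):
        cs = generate_complex(small_spec, rng, f"bf_{i}").structure
        assert np.array_equal(label_epitopes(cs).labels, brute_force_labels(cs))


def test_labels_invariant_under_joint_rigid_transform(small_sample):
    cs = small_sample.structure
    rot = special_ortho_group.rvs(3, random_state=np.random.default_rng(3))
    shift = np.array([5.0, -2.0, 11.0])
    moved = ComplexStructure(cs.antigen.transformed(rot, shift),
                             cs.antibody.transformed(rot, shift))
    assert np.array_equal(label_epitopes(moved).labels,
                          label_epitopes(cs).labels)


def test_interface_sets_empty_when_chains_far_apart(small_sample):
    cs = small_sample.structure
    far = ComplexStructure(cs.antigen,
                           cs.antibody.transformed(translation=[500.0, 0, 0]))
    ag_set, ab_set = interface_residues(far)
    assert len(ag_set) == 0 and len(ab_set) == 0


def test_epitope_residues_subset_of_interface_residues(small_spec):
    rng = np.random.default_rng(99)
    for i in range(5):
        cs = generate_complex(small_spec, rng, f"sub_{i}").structure
        epitope = set(np.flatnonzero(label_epitopes(cs).labels))
        ag_iface, _ = interface_residues(cs)
        assert epitope <= set(ag_iface)


def test_interface_matches_brute_force(small_sample):
    cs = small_sample.structure
    d = cdist(cs.antigen.coords, cs.antibody.coords)
    ag_expect = np.unique(cs.antigen.atom_residue_index[
        np.flatnonzero((d <= 8.0).any(axis=1))])
    ab_expect = np.unique(cs.antibody.atom_residue_index[
        np.flatnonzero((d <= 8.0).any(axis=0))])
    ag_set, ab_set = interface_residues(cs)
    assert np.array_equal(ag_set, ag_expect)
    assert np.array_equal(ab_set, ab_expect)


def test_pdb_round_trip_preserves_coordinates(small_sample, tmp_path):
    cs = small_sample.structure
    path = write_fixture_pdb(cs, tmp_path / "rt.pdb")
    back = parse_pdb(path, ["A"], ["H"], complex_id="rt")
    assert back.antigen.n_residues == cs.antigen.n_residues
    assert np.allclose(back.antigen.coords, cs.antigen.coords, atol=1e-3)
    assert np.allclose(back.antibody.coords, cs.antibody.coords, atol=1e-3)
    assert np.array_equal(back.antigen.residue_starts, cs.antigen.residue_starts)
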