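import numpy as np
import pytest
from rdkit import Chem

from molfoundry.graphs import (
    MolecularGraph,
    MolParseError,
    VocabularyError,
    canonical_key,
    featurize_atoms,
    load_structures,
    parse_smiles,
    strip_chirality,
)
from molfoundry.fixtures import write_cif_structure, write_sdf


@pytest.mark.parametrize(
    "smiles,n_atoms,n_bonds",
    [("O", 1, 0), ("C1CC1", 3, 3), ("CCO", 3, 2), ("c1ccccc1", 6, 6)],
)
def test_parse_smiles_counts(smiles, n_atoms, n_bonds):
    g = parse_smiles(smiles)
    assert g.n_atoms == n_atoms
    assert len(g.bonds) == n_bonds


def test_cyclopropane_degrees():
    g = parse_smiles("C1CC1")
    assert all(a.degree == 2 for a in g.atoms)
    assert all(len(g.neighbors(i)) == 2 for i in range(3))


def test_alanine_has_one_chiral_center():
    smiles = "N[C@@H](C)C(=O)O"
    g = parse_smiles(smiles)
    tagged = [a for a in g.atoms if a.chiral_tag != "none"]
    assert len(tagged) == 1
    # independent stereo perception on the same input
    centers = Chem.FindMolChiralCenters(Chem.MolFromSmiles(smiles))
    assert len(centers) == 1


def test_chirality_flag_off_clears_tags():
    g = parse_smiles("N[C@@H](C)C(=O)O", include_chirality=False)
    assert all(a.chiral_tag == "none" for a in g.atoms)


@pytest.mark.parametrize("bad", ["", "not_a_smiles((", "C(C)(C)(C)(C)C"])
def test_parse_errors_identify_input(bad):
    with pytest.raises(MolParseError):
        parse_smiles(bad)


def test_benzene_features_identical_rows():
    F = featurize_atoms(parse_smiles("c1ccccc1"))
    assert np.ptp(F.values, axis=0).max() == 0


def test_one_hot_blocks_sum_to_one():
    F = featurize_atoms(parse_smiles("N[C@@H](C)C(=O)O"))
    n_el = sum(1 for n in F.feature_names if n.startswith("element="))
    assert np.allclose(F.values[:, :n_el].sum(axis=1), 1.0)
    assert np.allclose(F.values[:, -3:].sum(axis=1), 1.0)


def test_enantiomer_features_differ_only_in_chiral_block():
    a = featurize_atoms(parse_smiles("C[C@H](N)O"))
    b = featurize_atoms(parse_smiles("C[C@@H](N)O"))
    diff_cols = np.where((a.values != b.values).any(axis=0))[0]
    assert len(diff_cols) > 0
    assert all(a.feature_names[c].startswith("chiral=") for c in diff_cols)
    # and with chirality disabled the graphs are identical
    ga = parse_smiles("C[C@H](N)O", include_chirality=False)
    gb = parse_smiles("C[C@@H](N)O", include_chirality=False)
    assert ga.to_json().replace("[C@H]", "").replace("[C@@H]", "") == \
           gb.to_json().replace("[C@H]", "").replace("[C@@H]", "")
    assert np.array_equal(featurize_atoms(ga).values, featurize_atoms(gb).values)


def test_featurization_is_pure():
    g = parse_smiles("CC(=O)NC")
    assert np.array_equal(featurize_atoms(g).values, featurize_atoms(g).values)


def test_out_of_vocabulary_error_names_element():
    g = parse_smiles("CCS")
    with pytest.raises(VocabularyError, match="'S'"):
        featurize_atoms(g, vocabulary=("C", "O"))


@pytest.mark.parametrize("smiles", ["CCO", "N[C@@H](C)C(=O)O", "c1ccc2ccccc2c1", "CC(=O)[O-]"])
def test_json_round_trip(smiles):
    g = parse_smiles(smiles)
    g2 = MolecularGraph.from_json(g.to_json())
    assert [a.element for a in g2.atoms] == [a.element for a in g.atoms]
    assert [a.chiral_tag for a in g2.atoms] == [a.chiral_tag for a in g.atoms]
    assert sorted(b.endpoints for b in g2.bonds) == sorted(b.endpoints for b in g.bonds)
    assert canonical_key(g2) == canonical_key(g)


def test_duplicate_bond_rejected():
    from molfoundry.graphs import AtomRecord, BondRecord

    atoms = [AtomRecord("C"), AtomRecord("C")]
    with pytest.raises(ValueError, match="duplicate"):
        MolecularGraph(atoms, [BondRecord((0, 1)), BondRecord((0, 1), "double")])


def test_sdf_load_counts_and_rejects(tmp_path, molset):
    path = tmp_path / "mix.sdf"
    write_sdf(molset[:2], path)
    text = path.read_text()
    # append a corrupt record: a bond row pointing at a nonexistent atom
    block = text.split("$$$$\n")[0]
    lines = block.splitlines()
    lines[-1] = lines[-1]  # keep M  END
    corrupt = block.replace("M  END", "  1 99  1  0\nM  END")
    path.write_text(text + corrupt + "$$$$\n")
    entries, rejects = load_structures(path, "sdf")
    assert len(entries) == 2
    assert len(rejects) == 1


def test_sdf_alignment_and_connectivity_round_trip(tmp_path, molset):
    path = tmp_path / "set.sdf"
    write_sdf(molset[:5], path)
    entries, rejects = load_structures(path, "sdf")
    assert not rejects
    for (g1, c1), (g0, c0) in zip(entries, molset[:5]):
        assert c1.shape == (g1.n_atoms, 3)
        # connectivity round-trips; stereo may be perceived from 3D on read
        assert canonical_key(strip_chirality(g1)) == canonical_key(strip_chirality(g0))


def test_cif_round_trip_matches_source_smiles(tmp_path):
    path = tmp_path / "mol.cif"
    write_cif_structure("CCO", path, seed=7)
    entries, rejects = load_structures(path, "cif")
    assert not rejects
    graph, coords = entries[0]
    assert canonical_key(graph) == canonical_key(parse_smiles("CCO"))
    assert coords.shape == (graph.n_atoms, 3)


def test_missing_file_raises_io_error():
    with pytest.raises(IOError):
        load_structures("no/such/file.sdf", "sdf")
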