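import numpy as np
import pytest

from molfoundry.curation import (
    AMBIGUOUS_BONDING_FLAG,
    SplitPlan,
    audit_split,
    bemis_murcko_scaffold,
    filter_ambiguous_and_polymorphs,
    filter_rare_elements,
    heavy_atom_rmsd,
    kfold_unseen,
    leave_component_out_split,
    scaffold_split,
)
from molfoundry.graphs import MolecularGraph, parse_smiles
from molfoundry.heads import ReactionRecord


def test_rare_element_toy_example():
    mols = [parse_smiles(s) for s in ("CCO", "CCS", "CCO")]
    kept, dropped = filter_rare_elements(mols, min_count=2)
    assert len(kept) == 2 and len(dropped) == 1
    assert any(a.element == "S" for a in dropped[0].atoms)


def test_rare_element_vacuous_threshold():
    mols = [parse_smiles(s) for s in ("CCO", "CCS")]
    kept, dropped = filter_rare_elements(mols, min_count=0)
    assert len(kept) == 2 and not dropped


def test_rare_element_filter_idempotent():
    mols = [parse_smiles(s) for s in ("CCO", "CCS", "CCO", "CCCl", "CC")]
    kept, _ = filter_rare_elements(mols, min_count=2)
    kept2, dropped2 = filter_rare_elements(kept, min_count=2)
    assert kept2 == kept and not dropped2


def _kabsch_rmsd_oracle(a, b):
    """Independent Kabsch superposition via SVD."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(b.T @ a)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return float(np.sqrt(np.mean(np.sum((a - b @ rot) ** 2, axis=1))))


def test_rmsd_matches_independent_kabsch(molset):
    rng = np.random.default_rng(0)
    for g, c in molset[:5]:
        perturbed = c + rng.normal(scale=0.3, size=c.shape)
        assert heavy_atom_rmsd(c, perturbed) == pytest.approx(
            _kabsch_rmsd_oracle(c, perturbed), abs=1e-8
        )


def test_identical_conformers_kept():
    g = parse_smiles("CCCCC")
    c = np.column_stack([np.arange(5) * 1.5, np.zeros(5), np.zeros(5)])
    kept, dropped = filter_ambiguous_and_polymorphs([(g, c), (g, c.copy())])
    assert len(kept) == 2 and not dropped


def test_divergent_polymorph_group_dropped():
    g = parse_smiles("CCCCC")
    extended = np.column_stack([np.arange(5) * 1.5, np.zeros(5), np.zeros(5)])
    curled = np.array(
        [[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0, 1.5, 0], [0, 1.5, 1.5]], float
    )
    assert _kabsch_rmsd_oracle(extended, curled) > 1.0
    kept, dropped = filter_ambiguous_and_polymorphs(
        [(g, extended), (g, curled)], rmsd_threshold=1.0
    )
    assert not kept and len(dropped) == 2


def test_ambiguous_bonding_flag_dropped_with_reason():
    g = parse_smiles("CC")
    flagged = MolecularGraph(g.atoms, g.bonds, flags=frozenset({AMBIGUOUS_BONDING_FLAG}))
    c = np.array([[0, 0, 0], [1.5, 0, 0]], float)
    kept, dropped = filter_ambiguous_and_polymorphs([(flagged, c)])
    assert not kept
    assert dropped[0][1] == "ambiguous bonding"


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

BENZENES = ["c1ccccc1C", "c1ccccc1CC", "c1ccccc1O", "c1ccccc1N", "c1ccccc1F"]
CYCLOHEXANES = ["C1CCCCC1C", "C1CCCCC1CC", "C1CCCCC1O", "C1CCCCC1N", "C1CCCCC1F"]


def test_scaffold_split_two_groups_land_apart():
    mols = [parse_smiles(s) for s in BENZENES + CYCLOHEXANES]
    plan = scaffold_split(mols, test_fraction=0.5, seed=0)
    scaf = [bemis_murcko_scaffold(m) for m in mols]
    train_scafs = {scaf[i] for i in plan.train_ids}
    test_scafs = {scaf[i] for i in plan.test_ids}
    assert not train_scafs & test_scafs
    assert len(plan.train_ids) == 5 and len(plan.test_ids) == 5


def test_scaffold_split_greedy_small_group_to_test():
    # 3 scaffolds of sizes 5 / 3 / 2, fraction 0.2 -> test is the size-2 group
    mols = [parse_smiles(s) for s in BENZENES + CYCLOHEXANES[:3] + ["c1ccncc1C", "c1ccncc1O"]]
    plan = scaffold_split(mols, test_fraction=0.2, seed=3)
    assert sorted(plan.test_ids) == [8, 9]


def test_scaffold_split_single_scaffold_errors():
    mols = [parse_smiles(s) for s in BENZENES]
    with pytest.raises(ValueError):
        scaffold_split(mols, test_fraction=0.5, seed=0)


def test_kfold_unseen_even_folds():
    mols = [parse_smiles(s) for s in BENZENES + CYCLOHEXANES]
    plans = kfold_unseen(mols, k=5, seed=1)
    assert len(plans) == 5
    assert all(len(p.test_ids) == 2 for p in plans)
    tests = [set(p.test_ids) for p in plans]
    assert set().union(*tests) == set(range(10))
    for i in range(5):
        for j in range(i + 1, 5):
            assert not tests[i] & tests[j]


def test_kfold_duplicates_share_a_fold():
    mols = [parse_smiles(s) for s in BENZENES + CYCLOHEXANES[:4] + ["CC(C)c1ccccc1C"]]
    mols.append(parse_smiles("Cc1ccccc1C(C)C"))  # same structure, different SMILES
    plans = kfold_unseen(mols, k=3, seed=0)
    dup_ids = {9, 10}
    for p in plans:
        test = set(p.test_ids)
        assert dup_ids <= test or not dup_ids & test


def _toy_reactions():
    recs = []
    for i in range(6):
        recs.append(ReactionRecord({"electrophile": f"{'C' * (i + 1)}Br", "ligand": "CP(C)C"}, 50.0))
    for i in range(4):
        recs.append(ReactionRecord({"electrophile": f"{'C' * (i + 1)}I", "ligand": "CCP(CC)CC"}, 60.0))
    return recs


def test_leave_component_out_partitions_by_usage():
    recs = _toy_reactions()
    plans = leave_component_out_split(recs, "ligand", ["CP(C)C"])
    plan = plans[0]
    assert len(plan.test_ids) == 6 and len(plan.train_ids) == 4
    assert all(recs[i].components["ligand"] == "CP(C)C" for i in plan.test_ids)
    audit_split(plan, recs)


def test_leave_component_out_absent_component_errors():
    with pytest.raises(ValueError, match="Pd"):
        leave_component_out_split(_toy_reactions(), "ligand", ["Pd"])


def test_leave_component_out_ubiquitous_component_errors():
    recs = [ReactionRecord({"ligand": "CP(C)C"}, 10.0) for _ in range(3)]
    with pytest.raises(ValueError, match="empty"):
        leave_component_out_split(recs, "ligand", ["CP(C)C"])


def test_split_plan_json_round_trip():
    plan = SplitPlan("leave_component_out", [0, 1], [2, 3], held_out=("ligand", "CP(C)C"))
    plan2 = SplitPlan.from_json(plan.to_json())
    assert plan2.train_ids == plan.train_ids
    assert plan2.held_out == plan.held_out


def test_split_plan_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        SplitPlan("scaffold", [0, 1], [1, 2])
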