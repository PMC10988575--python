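import numpy as np
import pytest

from molfoundry.backbone import BackboneConfig, init_backbone
from molfoundry.graphs import parse_smiles, strip_chirality
from molfoundry.heads import (
    HEAD_PRESETS,
    HeadSpec,
    ReactionRecord,
    encode_reaction,
    finetune,
    head_param_count,
    load_composite,
    predict_topk,
    save_composite,
    strip_and_attach,
)
from molfoundry.metrics import summarize_runs

CFG = BackboneConfig(hidden_dim=16, message_steps=2, readout_dim=12)


@pytest.fixture(scope="module")
def backbone():
    return init_backbone(CFG)


@pytest.mark.parametrize(
    "spec,expected",
    [
        (HeadSpec("regression", 256, 120, 1), 30961),
        (HeadSpec("regression", 1, 1, 1), 4),
        (HeadSpec("multilabel", 256, 86, 113), 256 * 86 + 86 + 86 * 113 + 113),
    ],
)
def test_head_param_count_closed_form(spec, expected):
    assert head_param_count(spec) == expected


@pytest.mark.parametrize(
    "preset,target",
    [("toxicity", 32_000), ("odor", 32_000), ("yield_base", 260_000), ("yield_large", 1_000_000)],
)
def test_presets_land_near_published_budgets(preset, target):
    count = head_param_count(HEAD_PRESETS[preset])
    assert abs(count - target) / target <= 0.15


def test_attach_is_seeded_and_frozen(backbone):
    spec = HeadSpec("regression", 12, 8, 1)
    before = backbone.fingerprint
    a = strip_and_attach(backbone, spec, seed=3)
    b = strip_and_attach(backbone, spec, seed=3)
    c = strip_and_attach(backbone, spec, seed=4)
    assert a.head_fingerprint() == b.head_fingerprint()
    assert a.head_fingerprint() != c.head_fingerprint()
    assert backbone.fingerprint == before


def test_attach_checks_input_dimension(backbone):
    with pytest.raises(ValueError, match="input_dim"):
        strip_and_attach(backbone, HeadSpec("regression", 99, 8, 1), seed=0)


def test_composite_has_no_geometry_head(backbone):
    comp = strip_and_attach(backbone, HeadSpec("regression", 12, 8, 1), seed=0)
    assert not hasattr(comp, "predict_geometry")


def test_encode_reaction_padding_and_role_order(backbone):
    roles = ("electrophile", "ligand", "base")
    comp = strip_and_attach(
        backbone, HeadSpec("regression", 36, 8, 1), seed=0, reaction_roles=roles
    )
    rec = ReactionRecord({"ligand": "CP(C)C"})
    v = encode_reaction(rec, comp)
    assert v.shape == (36,)
    assert np.all(v[:12] == 0) and np.all(v[24:] == 0)
    assert np.any(v[12:24] != 0)
    # mapping key order is irrelevant
    r1 = ReactionRecord({"electrophile": "CBr", "base": "CCN(CC)CC"})
    r2 = ReactionRecord({"base": "CCN(CC)CC", "electrophile": "CBr"})
    assert np.array_equal(encode_reaction(r1, comp), encode_reaction(r2, comp))


def test_reactions_differing_only_in_ligand_differ_only_in_ligand_block(backbone):
    roles = ("electrophile", "ligand", "base")
    comp = strip_and_attach(
        backbone, HeadSpec("regression", 36, 8, 1), seed=0, reaction_roles=roles
    )
    r1 = ReactionRecord({"electrophile": "CBr", "ligand": "CP(C)C", "base": "CCN(CC)CC"})
    r2 = ReactionRecord({"electrophile": "CBr", "ligand": "CCP(CC)CC", "base": "CCN(CC)CC"})
    v1, v2 = encode_reaction(r1, comp), encode_reaction(r2, comp)
    assert np.array_equal(v1[:12], v2[:12])
    assert np.array_equal(v1[24:], v2[24:])
    assert not np.array_equal(v1[12:24], v2[12:24])


def test_unparseable_component_names_role(backbone):
    comp = strip_and_attach(
        backbone, HeadSpec("regression", 12, 8, 1), seed=0, reaction_roles=("ligand",)
    )
    with pytest.raises(ValueError, match="ligand"):
        encode_reaction(ReactionRecord({"ligand": "((("}), comp)


def test_finetune_never_touches_backbone(backbone, molset):
    graphs = [g for g, _ in molset[:10]]
    y = np.arange(10, dtype=float)
    before = backbone.fingerprint
    comp = strip_and_attach(backbone, HeadSpec("regression", 12, 8, 1), seed=0)
    finetune(comp, graphs, y, epochs=10, seed=0)
    assert comp.backbone.fingerprint == before


def test_finetune_rejects_mismatched_targets(backbone, molset):
    graphs = [g for g, _ in molset[:4]]
    comp = strip_and_attach(backbone, HeadSpec("regression", 12, 8, 1), seed=0)
    with pytest.raises(ValueError):
        finetune(comp, graphs, np.zeros((4, 3)), epochs=1)
    ml = strip_and_attach(backbone, HeadSpec("multilabel", 12, 8, 5), seed=0)
    with pytest.raises(ValueError):
        finetune(ml, graphs, np.zeros((4, 3)), epochs=1)


def test_multiseed_runs_distinct_and_summarized(backbone, molset):
    graphs = [g for g, _ in molset[:10]]
    y = np.linspace(0, 1, 10)
    prints, scores = [], []
    for s in range(5):
        comp = strip_and_attach(backbone, HeadSpec("regression", 12, 8, 1), seed=s)
        comp, trace = finetune(comp, graphs, y, epochs=15, seed=s)
        prints.append(comp.head_fingerprint())
        scores.append(trace[-1])
    assert len(set(prints)) == 5
    mean, se = summarize_runs(scores)
    assert se >= 0 and np.isfinite(mean)


def test_predict_topk_tie_break_and_sorting(backbone, molset):
    comp = strip_and_attach(backbone, HeadSpec("multilabel", 12, 8, 3), seed=0)
    mol = molset[0][0]
    # uniform logits: tie-break by label index
    comp.head["W2"][:] = 0.0
    comp.head["b2"][:] = 0.0
    assert predict_topk(comp, mol, 2) == [0, 1]
    # hand-set logits -> sorted order
    comp.head["b2"][:] = [0.1, 0.9, 0.5]
    assert predict_topk(comp, mol, 2) == [1, 2]
    assert sorted(predict_topk(comp, mol, 3)) == [0, 1, 2]
    with pytest.raises(ValueError):
        predict_topk(comp, mol, 4)
    reg = strip_and_attach(backbone, HeadSpec("regression", 12, 8, 1), seed=0)
    with pytest.raises(ValueError):
        predict_topk(reg, mol, 1)


def test_enantiomers_identical_without_chirality(backbone, molset):
    graphs = [g for g, _ in molset[:10]]
    y = np.linspace(0, 1, 10)
    comp = strip_and_attach(backbone, HeadSpec("regression", 12, 8, 1), seed=0)
    comp, _ = finetune(comp, graphs, y, epochs=10, seed=0)
    a = strip_chirality(parse_smiles("C[C@H](N)CO"))
    b = strip_chirality(parse_smiles("C[C@@H](N)CO"))
    pa, pb = comp.predict([a]), comp.predict([b])
    assert pa[0] == pb[0]


def test_yield_predictions_clipped(backbone):
    comp = strip_and_attach(
        backbone, HeadSpec("regression", 12, 8, 1), seed=0, reaction_roles=("ligand",)
    )
    comp.target_loc, comp.target_scale = 500.0, 1.0  # force out-of-range raw output
    preds = comp.predict([ReactionRecord({"ligand": "CP(C)C"})])
    assert 0.0 <= preds[0] <= 100.0


def test_composite_save_load_round_trip(backbone, molset, tmp_path):
    graphs = [g for g, _ in molset[:8]]
    y = np.linspace(-1, 1, 8)
    comp = strip_and_attach(backbone, HeadSpec("regression", 12, 8, 1), seed=1)
    comp, _ = finetune(comp, graphs, y, epochs=10, seed=1)
    save_composite(comp, tmp_path / "head.npz")
    loaded, _ = load_composite(tmp_path / "head.npz", backbone)
    assert np.allclose(loaded.predict(graphs), comp.predict(graphs))
    other = init_backbone(BackboneConfig(hidden_dim=16, message_steps=2, readout_dim=12, seed=9))
    with pytest.raises(ValueError, match="fingerprint"):
        load_composite(tmp_path / "head.npz", other)
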