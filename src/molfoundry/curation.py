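"""Dataset curation filters and evaluation-split protocols.

Filters: molecules containing rare elements (fewer than ``min_count``
occurrences across the dataset, default 100) are excluded; records with
ambiguous bond perception are dropped; conformational polymorphs — multiple
deposited conformers of one molecule — are dropped wholesale when any pair
differs by more than an RMSD threshold after optimal superposition.

Splits: Bemis–Murcko scaffold splits (test molecules carry unseen
frameworks), k-fold cross-validation with unseen molecules per fold, and
leave-component-out splits for reaction tables (all reactions using a given
reagent in a given role form the test set).
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.spatial.transform import Rotation

from .graphs import MolecularGraph, canonical_key, graph_to_rdkit

if TYPE_CHECKING:  # pragma: no cover
    from .heads import ReactionRecord

AMBIGUOUS_BONDING_FLAG = "ambiguous_bonding"
DEFAULT_MIN_ELEMENT_COUNT = 100
DEFAULT_RMSD_THRESHOLD = 1.0  # Å


@dataclass
class SplitPlan:
    """A train/test partition with verifiable disjointness."""

    kind: str  # {scaffold, kfold_unseen, leave_component_out}
    train_ids: list
    test_ids: list
    held_out: tuple[str, str] | None = None  # (role, component) for reactions
    fold: int | None = None

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "train_ids": list(self.train_ids),
                "test_ids": list(self.test_ids),
                "held_out": list(self.held_out) if self.held_out else None,
                "fold": self.fold,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "SplitPlan":
        d = json.loads(payload)
        held = tuple(d["held_out"]) if d.get("held_out") else None
        return cls(d["kind"], d["train_ids"], d["test_ids"], held, d.get("fold"))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_rare_elements(
    dataset: Sequence[MolecularGraph], min_count: int = DEFAULT_MIN_ELEMENT_COUNT
) -> tuple[list[MolecularGraph], list[MolecularGraph]]:
    """Drop molecules containing any element seen < min_count times overall.

    Counts are per-atom occurrences over the whole dataset, computed before
    any molecule is dropped, so the operation is idempotent.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts: Counter = Counter()
    for g in dataset:
        counts.update(a.element for a in g.atoms)
    rare = {e for e, c in counts.items() if c < min_count}
    kept, dropped = [], []
    for g in dataset:
        (dropped if any(a.element in rare for a in g.atoms) else kept).append(g)
    return kept, dropped


def heavy_atom_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Best-fit RMSD after centroid removal and optimal (Kabsch) rotation."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shape")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if a.shape[0] == 1:
        return 0.0
    import warnings

    with warnings.catch_warnings():
        # planar/linear sets trigger a uniqueness warning; the RMSD is still valid
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(a.shape[0]))


def filter_ambiguous_and_polymorphs(
    structures: Sequence[tuple[MolecularGraph, np.ndarray]],
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
) -> tuple[list, list]:
    """Drop ambiguous-bonding records and divergent conformational polymorphs.

    Records flagged with failed/ambiguous bond perception are removed first.
    Remaining records are grouped by canonical graph; if any pair within a
    group exceeds ``rmsd_threshold`` Å best-fit heavy-atom RMSD, the whole
    group is removed (the conformations genuinely differ and neither can be
    taken as "the" geometry of that molecule).
    """
    if rmsd_threshold <= 0:
        raise ValueError("rmsd_threshold must be positive")
    kept: list = []
    dropped: list = []  # ((graph, coords), reason)
    groups: dict[str, list] = defaultdict(list)
    for graph, coords in structures:
        if AMBIGUOUS_BONDING_FLAG in graph.flags:
            dropped.append(((graph, coords), "ambiguous bonding"))
            continue
        groups[canonical_key(graph)].append((graph, coords))
    for key, members in groups.items():
        divergent = False
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if heavy_atom_rmsd(members[i][1], members[j][1]) > rmsd_threshold:
                    divergent = True
                    break
            if divergent:
                break
        if divergent:
            dropped.extend((m, f"conformational polymorphs of {key}") for m in members)
        else:
            kept.extend(members)
    return kept, dropped


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def _ids(dataset: Sequence[MolecularGraph]) -> list:
    return [g.name if g.name is not None else i for i, g in enumerate(dataset)]


def bemis_murcko_scaffold(graph: MolecularGraph) -> str:
    """Bemis–Murcko framework SMILES (empty string for acyclic molecules)."""
    return MurckoScaffold.MurckoScaffoldSmiles(mol=graph_to_rdkit(graph))


def scaffold_split(
    dataset: Sequence[MolecularGraph], test_fraction: float, seed: int
) -> SplitPlan:
    """Partition whole Bemis–Murcko scaffold groups into train and test.

    Groups are assigned to the training set greedily, largest first (ties
    shuffled by seed), until the training set reaches 1 - test_fraction of
    the data; the remaining groups form the test set, so no scaffold ever
    straddles the split.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    ids = _ids(dataset)
    groups: dict[str, list] = defaultdict(list)
    for g, gid in zip(dataset, ids):
        groups[bemis_murcko_scaffold(g)].append(gid)
    if len(groups) < 2:
        raise ValueError("cannot scaffold-split a single-scaffold dataset")
    rng = np.random.default_rng(seed)
    keys = list(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda k: -len(groups[k]))  # stable: seed breaks ties
    train_target = len(dataset) * (1.0 - test_fraction)
    train_ids: list = []
    test_ids: list = []
    for k in keys:
        if len(train_ids) < train_target:
            train_ids.extend(groups[k])
        else:
            test_ids.extend(groups[k])
    if not test_ids:
        # every group fit under the train target; hold out the smallest
        smallest = keys[-1]
        test_ids = groups[smallest]
        train_ids = [i for i in train_ids if i not in set(test_ids)]
    return SplitPlan("scaffold", train_ids, test_ids)


def kfold_unseen(
    dataset: Sequence[MolecularGraph], k: int, seed: int
) -> list[SplitPlan]:
    """k-fold CV where each fold's test molecules are unseen.

    Duplicate structures (identical canonical form) are always co-assigned to
    one fold so no molecule appears on both sides of any fold's split.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(dataset) < k:
        raise ValueError("dataset smaller than k")
    ids = _ids(dataset)
    groups: dict[str, list] = defaultdict(list)
    for g, gid in zip(dataset, ids):
        groups[canonical_key(g)].append(gid)
    rng = np.random.default_rng(seed)
    keys = list(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda kk: -len(groups[kk]))
    folds: list[list] = [[] for _ in range(k)]
    for kk in keys:  # largest groups first onto the currently smallest fold
        folds[min(range(k), key=lambda f: len(folds[f]))].extend(groups[kk])
    all_ids = set(ids)
    plans = []
    for f, test in enumerate(folds):
        train = sorted(all_ids - set(test), key=str)
        plans.append(SplitPlan("kfold_unseen", train, sorted(test, key=str), fold=f))
    return plans


def leave_component_out_split(
    reactions: Sequence["ReactionRecord"],
    role: str,
    components: Sequence[str] | None = None,
) -> list[SplitPlan]:
    """One plan per held-out component: test = all reactions using it in `role`."""
    usage: dict[str, list[int]] = defaultdict(list)
    for i, rec in enumerate(reactions):
        comp = rec.components.get(role)
        if comp is not None:
            usage[comp].append(i)
    if components is None:
        components = sorted(usage)
    plans = []
    for comp in components:
        if comp not in usage:
            raise ValueError(f"component {comp!r} never occurs in role {role!r}")
        test = usage[comp]
        train = [i for i in range(len(reactions)) if i not in set(test)]
        if not train:
            raise ValueError(
                f"component {comp!r} occurs in every reaction; training set empty"
            )
        plans.append(
            SplitPlan("leave_component_out", train, test, held_out=(role, comp))
        )
    return plans


def top_component_splits(
    reactions: Sequence["ReactionRecord"], role: str, n_top: int = 1
) -> list[SplitPlan]:
    """Hold out the most-used components in a role (historical-data protocol)."""
    usage: Counter = Counter()
    for rec in reactions:
        comp = rec.components.get(role)
        if comp is not None:
            usage[comp] += 1
    top = [c for c, _ in usage.most_common(n_top)]
    return leave_component_out_split(reactions, role, top)


def audit_split(plan: SplitPlan, reactions: Sequence["ReactionRecord"] | None = None) -> None:
    """Raise if a plan leaks identifiers (or held-out components) train→test."""
    train, test = set(plan.train_ids), set(plan.test_ids)
    if train & test:
        raise ValueError("identifier leak between train and test")
    if plan.held_out is not None and reactions is not None:
        role, comp = plan.held_out
        for i in plan.train_ids:
            if reactions[i].components.get(role) == comp:
                raise ValueError(f"held-out component {comp!r} present in training set")
        for i in plan.test_ids:
            if reactions[i].components.get(role) != comp:
                raise ValueError(f"test reaction {i} lacks held-out component {comp!r}")
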