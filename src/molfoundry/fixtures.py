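"""Synthetic molecules, conformers, and task labels with known ground truth.

Everything the framework needs can be generated here without downloads:

* small organic molecules assembled at random (valence-respecting trees with
  optional unsaturation and ring closures) and embedded as single
  distance-geometry conformers relaxed with a force field — a documented
  surrogate for experimental crystal geometries;
* regression labels that are a stored linear function of simple graph
  descriptors or of a frozen backbone's latent vector, plus Gaussian noise —
  so head finetuning can be checked by parameter recovery;
* multilabel class assignments driven by stored structural rules (ring
  presence, heteroatoms, size, ...), with a configurable minority of
  all-zero rows mimicking label-free molecules;
* factorial reaction tables whose yields follow a stored additive function of
  component descriptors, with optional noise and zero-yield "negative
  reactions".

All outputs are exactly reproducible from (config, seed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import networkx as nx
from rdkit import Chem
from rdkit.Chem import AllChem

from .backbone import BackboneParams, latent_vector
from .graphs import (
    MolecularGraph,
    graph_from_rdkit,
    graph_to_rdkit,
    parse_smiles,
)
from .heads import ROLE_ORDER, ReactionRecord
from .metrics import LabelMatrix

logger = logging.getLogger(__name__)

_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "Cl": 1, "Br": 1, "P": 3}


@dataclass(frozen=True)
class FixtureConfig:
    n_molecules: int = 50
    seed: int = 0
    element_palette: tuple[str, ...] = ("C", "N", "O", "F", "S", "Cl")
    size_range: tuple[int, int] = (4, 12)
    label_model: str = "linear_on_descriptors"  # or "linear_on_latent"
    noise_sd: float = 0.0
    n_corrupt: int = 0  # records given overlapping atoms, for reject-path tests

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.label_model not in ("linear_on_descriptors", "linear_on_latent"):
            raise ValueError(f"unknown label_model {self.label_model!r}")
        unknown = [e for e in self.element_palette if e not in _VALENCE]
        if unknown:
            raise ValueError(f"elements without valence data: {unknown}")


# ---------------------------------------------------------------------------
# Molecule assembly
# ---------------------------------------------------------------------------

def _assemble_random_mol(rng: np.random.Generator, palette, size_range) -> Chem.Mol | None:
    """Random valence-respecting molecule: tree + optional unsaturation + ring."""
    n_heavy = int(rng.integers(size_range[0], size_range[1] + 1))
    # weight carbon heavily so the sets look organic
    weights = np.array([4.0 if e == "C" else 1.0 for e in palette])
    weights /= weights.sum()
    rw = Chem.RWMol()
    free = []
    first = "C"  # guarantee a carbon-containing molecule
    rw.AddAtom(Chem.Atom(first))
    free.append(_VALENCE[first])
    for _ in range(n_heavy - 1):
        sym = str(rng.choice(palette, p=weights))
        candidates = [i for i, f in enumerate(free) if f >= 1]
        if not candidates:
            break
        host = int(rng.choice(candidates))
        idx = rw.AddAtom(Chem.Atom(sym))
        rw.AddBond(host, idx, Chem.BondType.SINGLE)
        free[host] -= 1
        free.append(_VALENCE[sym] - 1)
    # unsaturation: upgrade a few single bonds where both ends allow it
    for bond in list(rw.GetBonds()):
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if free[i] >= 1 and free[j] >= 1 and rng.random() < 0.15:
            bond.SetBondType(Chem.BondType.DOUBLE)
            free[i] -= 1
            free[j] -= 1
    # one ring closure between valence-free atoms at graph distance >= 2
    if rng.random() < 0.5:
        dmat = Chem.GetDistanceMatrix(rw.GetMol())
        pairs = [
            (i, j)
            for i in range(rw.GetNumAtoms())
            for j in range(i + 1, rw.GetNumAtoms())
            if free[i] >= 1 and free[j] >= 1 and 2 <= dmat[i, j] <= 5
        ]
        if pairs:
            i, j = pairs[int(rng.integers(len(pairs)))]
            rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _embed_with_h(mol: Chem.Mol, seed: int) -> Chem.Mol | None:
    """One ETKDG conformer, force-field relaxed; returns the H-explicit mol."""
    mh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mh, params) != 0:
        return None
    try:
        if AllChem.MMFFHasAllMoleculeParams(mh):
            AllChem.MMFFOptimizeMolecule(mh, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(mh, maxIters=500)
    except Exception:
        return None
    return mh


def generate_molecule_set(
    config: FixtureConfig,
) -> list[tuple[MolecularGraph, np.ndarray]]:
    """Random small molecules, each with one relaxed 3D conformer.

    Deterministic in the config seed; embedding failures are logged and the
    molecule resampled.  With ``n_corrupt > 0`` the first records are given
    two overlapping atoms so downstream geometry extraction rejects them.
    """
    rng = np.random.default_rng(config.seed)
    out: list[tuple[MolecularGraph, np.ndarray]] = []
    attempts = 0
    while len(out) < config.n_molecules:
        attempts += 1
        if attempts > 50 * config.n_molecules:
            raise RuntimeError("molecule assembly keeps failing; check the palette")
        embed_seed = int(rng.integers(1, 2**31 - 1))
        mol = _assemble_random_mol(rng, config.element_palette, config.size_range)
        if mol is None:
            continue
        mh = _embed_with_h(mol, embed_seed)
        if mh is None:
            logger.info("embedding failed; resampling molecule")
            continue
        heavy = Chem.RemoveHs(mh)
        coords = np.array(heavy.GetConformer().GetPositions(), dtype=float)
        graph, order = graph_from_rdkit(
            heavy, include_chirality=True, name=f"fix{len(out):04d}"
        )
        out.append((graph, coords[order]))
    for k in range(min(config.n_corrupt, len(out))):
        graph, coords = out[k]
        if graph.n_atoms >= 2:
            bad = coords.copy()
            j = graph.neighbors(0)[0]
            bad[j] = bad[0]  # overlapping bonded atoms: degenerate geometry
            out[k] = (graph, bad)
    return out


# ---------------------------------------------------------------------------
# Descriptors and labels
# ---------------------------------------------------------------------------

def graph_descriptors(graph: MolecularGraph) -> np.ndarray:
    """(atom count, ring count, heteroatom count) — the simple label basis."""
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_atoms))
    g.add_edges_from(b.endpoints for b in graph.bonds)
    n_rings = len(graph.bonds) - graph.n_atoms + nx.number_connected_components(g)
    n_hetero = sum(1 for a in graph.atoms if a.element != "C")
    return np.array([graph.n_atoms, n_rings, n_hetero], dtype=float)


def generate_regression_labels(
    molecules,
    config: FixtureConfig,
    backbone: BackboneParams | None = None,
) -> tuple[np.ndarray, dict]:
    """Labels linear in descriptors or in a frozen latent, plus Gaussian noise.

    Returns (labels, record); the record stores coefficients, intercept and
    the individual noise draws so the labels are exactly recomputable.
    """
    graphs = [m[0] if isinstance(m, tuple) else m for m in molecules]
    rng = np.random.default_rng(config.seed + 1)
    if config.label_model == "linear_on_latent":
        if backbone is None:
            raise ValueError("linear_on_latent labels need a backbone")
        Z = np.stack([latent_vector(g, backbone) for g in graphs])
    else:
        Z = np.stack([graph_descriptors(g) for g in graphs])
    # standardize the basis so labels come out with O(1) spread
    loc = Z.mean(axis=0)
    scale = np.maximum(Z.std(axis=0), 1e-8)
    Zs = (Z - loc) / scale
    coef = rng.normal(size=Z.shape[1]) / np.sqrt(Z.shape[1])
    intercept = float(rng.normal())
    noise = rng.normal(scale=config.noise_sd, size=Z.shape[0]) if config.noise_sd else np.zeros(Z.shape[0])
    labels = Zs @ coef + intercept + noise
    record = {
        "label_model": config.label_model,
        "coefficients": coef.tolist(),
        "intercept": intercept,
        "basis_loc": loc.tolist(),
        "basis_scale": scale.tolist(),
        "noise_sd": config.noise_sd,
        "noise": noise.tolist(),
    }
    return labels, record


_RULE_KINDS = ("has_ring", "has_element", "min_atoms", "has_multiple_bond", "min_hydrogens")


def _rule_applies(graph: MolecularGraph, rule: dict) -> bool:
    kind, param = rule["kind"], rule.get("param")
    if kind == "has_ring":
        return graph_descriptors(graph)[1] > 0
    if kind == "has_element":
        return any(a.element == param for a in graph.atoms)
    if kind == "min_atoms":
        return graph.n_atoms >= param
    if kind == "has_multiple_bond":
        return any(b.order in ("double", "triple", "aromatic") for b in graph.bonds)
    if kind == "min_hydrogens":
        return sum(a.n_hydrogens for a in graph.atoms) >= param
    raise ValueError(f"unknown rule kind {kind!r}")


def apply_label_rules(molecules, record: dict) -> LabelMatrix:
    """Reapply a stored rule record; reproduces the generated matrix exactly."""
    graphs = [m[0] if isinstance(m, tuple) else m for m in molecules]
    mat = np.zeros((len(graphs), len(record["rules"])), dtype=int)
    for i, g in enumerate(graphs):
        for j, rule in enumerate(record["rules"]):
            mat[i, j] = int(_rule_applies(g, rule))
    for i in record["zeroed_rows"]:
        mat[i, :] = 0
    return LabelMatrix(mat, record["class_names"])


def generate_multilabel_labels(
    molecules, n_classes: int, rule_seed: int, zero_fraction: float = 0.1
) -> tuple[LabelMatrix, dict]:
    """Assign classes by stored structural rules; zero a minority of rows.

    Bayes-optimal labels are known (the rules themselves), so learnability
    checks have ground truth.  The all-zero rows emulate molecules with no
    detectable label at all.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    graphs = [m[0] if isinstance(m, tuple) else m for m in molecules]
    rng = np.random.default_rng(rule_seed)
    elements = ["O", "N", "S", "F", "Cl"]
    rules = []
    for j in range(n_classes):
        kind = _RULE_KINDS[j % len(_RULE_KINDS)]
        if kind == "has_element":
            rule = {"kind": kind, "param": elements[int(rng.integers(len(elements)))]}
        elif kind == "min_atoms":
            rule = {"kind": kind, "param": int(rng.integers(5, 11))}
        elif kind == "min_hydrogens":
            rule = {"kind": kind, "param": int(rng.integers(6, 16))}
        else:
            rule = {"kind": kind, "param": None}
        rules.append(rule)
    n_zero = int(np.floor(zero_fraction * len(graphs)))
    zeroed = sorted(int(i) for i in rng.choice(len(graphs), size=n_zero, replace=False))
    record = {
        "rules": rules,
        "zeroed_rows": zeroed,
        "class_names": [f"class_{j}" for j in range(n_classes)],
        "zero_fraction": zero_fraction,
    }
    return apply_label_rules(graphs, record), record


# ---------------------------------------------------------------------------
# Reaction tables
# ---------------------------------------------------------------------------

def _component_effect(smiles: str, a: float, b: float) -> float:
    d = graph_descriptors(parse_smiles(smiles))
    return a * d[0] + b * d[2]  # atom count and heteroatom count


def generate_reaction_table(
    role_palettes: dict[str, list[str]],
    seed: int,
    n_reactions: int | None = None,
    noise_sd: float = 0.0,
    negative_fraction: float = 0.0,
) -> tuple[list[ReactionRecord], dict]:
    """Factorial (or subsampled) reaction table with rule-generated yields.

    yield = clip(base + Σ_role (a_role·atoms + b_role·heteroatoms), 0, 100)
    plus optional noise; a configurable fraction is forced to 0% to emulate
    failed ("negative") reactions.  The additive rule is returned so yields
    are exactly recomputable when noise_sd = 0.
    """
    if not role_palettes:
        raise ValueError("role_palettes must not be empty")
    unknown = set(role_palettes) - set(ROLE_ORDER)
    if unknown:
        raise ValueError(f"unknown roles: {sorted(unknown)}")
    roles = [r for r in ROLE_ORDER if r in role_palettes]
    rng = np.random.default_rng(seed)
    combos = list(itertools.product(*(role_palettes[r] for r in roles)))
    if n_reactions is not None and n_reactions < len(combos):
        idx = rng.choice(len(combos), size=n_reactions, replace=False)
        combos = [combos[int(i)] for i in sorted(idx)]
    rule = {
        "base": float(rng.uniform(35, 65)),
        "coefficients": {r: [float(rng.uniform(-3, 3)), float(rng.uniform(-5, 5))] for r in roles},
    }
    records = []
    for combo in combos:
        components = dict(zip(roles, combo))
        y = rule["base"] + sum(
            _component_effect(smi, *rule["coefficients"][r])
            for r, smi in components.items()
        )
        if noise_sd:
            y += float(rng.normal(scale=noise_sd))
        records.append(ReactionRecord(components, float(np.clip(y, 0.0, 100.0))))
    n_neg = int(np.floor(negative_fraction * len(records)))
    negatives = sorted(int(i) for i in rng.choice(len(records), size=n_neg, replace=False)) if n_neg else []
    for i in negatives:
        records[i].yield_percent = 0.0
    rule["negative_rows"] = negatives
    rule["roles"] = roles
    return records, rule


def recompute_yield(record: ReactionRecord, rule: dict) -> float:
    """Noiseless yield implied by a stored rule (before negative-row zeroing)."""
    y = rule["base"] + sum(
        _component_effect(smi, *rule["coefficients"][r])
        for r, smi in record.components.items()
        if r in rule["coefficients"]
    )
    return float(np.clip(y, 0.0, 100.0))


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_sdf(structures, path) -> None:
    """Write (graph, coords) pairs as an SDF (V2000) file."""
    writer = Chem.SDWriter(str(path))
    try:
        for graph, coords in structures:
            mol = graph_to_rdkit(graph)
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, xyz in enumerate(np.asarray(coords, dtype=float)):
                conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
            mol.AddConformer(conf)
            if graph.name:
                mol.SetProp("_Name", graph.name)
            writer.write(mol)
    finally:
        writer.close()


def write_cif_structure(smiles: str, path, seed: int = 7, cell: float = 30.0) -> None:
    """Embed a molecule and write a small-molecule CIF (P1 cell, all atoms)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    mh = _embed_with_h(mol, seed)
    if mh is None:
        raise RuntimeError(f"could not embed {smiles!r}")
    pos = np.array(mh.GetConformer().GetPositions(), dtype=float)
    frac = (pos - pos.min(axis=0) + cell / 3.0) / cell
    lines = [
        "data_fixture",
        f"_cell_length_a {cell:.4f}",
        f"_cell_length_b {cell:.4f}",
        f"_cell_length_c {cell:.4f}",
        "_cell_angle_alpha 90",
        "_cell_angle_beta 90",
        "_cell_angle_gamma 90",
        "_symmetry_space_group_name_H-M 'P 1'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for i, atom in enumerate(mh.GetAtoms()):
        sym = atom.GetSymbol()
        lines.append(
            f"{sym}{i + 1} {sym} {frac[i, 0]:.6f} {frac[i, 1]:.6f} {frac[i, 2]:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_regression_csv(graphs, labels, path) -> None:
    import pandas as pd

    smiles = [g.source_smiles or _graph_smiles(g) for g in graphs]
    pd.DataFrame({"smiles": smiles, "label": labels}).to_csv(path, index=False)


def write_multilabel_csv(graphs, label_matrix: LabelMatrix, path) -> None:
    import pandas as pd

    smiles = [g.source_smiles or _graph_smiles(g) for g in graphs]
    joined = [
        ";".join(
            name for name, v in zip(label_matrix.class_names, row) if v
        )
        for row in label_matrix.values
    ]
    pd.DataFrame({"smiles": smiles, "labels": joined}).to_csv(path, index=False)


def write_reaction_csv(records, path) -> None:
    import pandas as pd

    rows = []
    for rec in records:
        row = {r: rec.components.get(r, "") for r in ROLE_ORDER}
        row["yield"] = rec.yield_percent
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _graph_smiles(graph: MolecularGraph) -> str:
    from .graphs import canonical_key

    return canonical_key(graph)
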