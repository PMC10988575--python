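"""Molecular graph parsing and featurization.

Molecules are represented as heavy-atom graphs: atoms carry element, formal
charge, heavy-atom degree, aromaticity, implicit-hydrogen count and a one-hot
tetrahedral chiral tag; bonds carry a categorical order (single / double /
triple / aromatic).  Atoms are renumbered into a chirality-agnostic canonical
order at parse time so that serialization is stable and enantiomer pairs share
an atom ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdDetermineBonds
import gemmi

RDLogger.DisableLog("rdApp.*")

#: Elements handled by default featurization; anything else is routed to the
#: rare-element curation pathway.
DEFAULT_VOCABULARY: tuple[str, ...] = (
    "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B", "Si",
)

CHIRAL_TAGS = ("none", "cw", "ccw")
BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RD_BOND_TO_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_ORDER_TO_RD_BOND = {v: k for k, v in _RD_BOND_TO_ORDER.items()}

_RD_CHI_TO_TAG = {
    Chem.ChiralType.CHI_UNSPECIFIED: "none",
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "cw",
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "ccw",
}
_TAG_TO_RD_CHI = {v: k for k, v in _RD_CHI_TO_TAG.items()}


class MolParseError(ValueError):
    """Raised when a molecular input cannot be parsed into a valid graph."""


class VocabularyError(ValueError):
    """Raised when a graph contains an element outside the feature vocabulary."""


@dataclass(frozen=True)
class AtomRecord:
    element: str
    formal_charge: int = 0
    degree: int = 0
    aromatic: bool = False
    n_hydrogens: int = 0
    chiral_tag: str = "none"

    def __post_init__(self) -> None:
        if self.chiral_tag not in CHIRAL_TAGS:
            raise ValueError(f"unknown chiral tag {self.chiral_tag!r}")


@dataclass(frozen=True)
class BondRecord:
    endpoints: tuple[int, int]
    order: str = "single"

    def __post_init__(self) -> None:
        i, j = self.endpoints
        if i == j:
            raise ValueError(f"self-bond on atom {i}")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph in canonical atom order."""

    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    name: str | None = None
    source_smiles: str | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            i, j = b.endpoints
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond {b.endpoints} outside atom range 0..{n - 1}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        """Bonded neighbors of atom i, ascending (canonical) index order."""
        out = []
        for b in self.bonds:
            a, c = b.endpoints
            if a == i:
                out.append(c)
            elif c == i:
                out.append(a)
        return sorted(out)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "atoms": [
                    {
                        "element": a.element,
                        "formal_charge": a.formal_charge,
                        "degree": a.degree,
                        "aromatic": a.aromatic,
                        "n_hydrogens": a.n_hydrogens,
                        "chiral_tag": a.chiral_tag,
                    }
                    for a in self.atoms
                ],
                "bonds": [
                    {"endpoints": list(b.endpoints), "order": b.order}
                    for b in self.bonds
                ],
                "name": self.name,
                "source_smiles": self.source_smiles,
                "flags": sorted(self.flags),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "MolecularGraph":
        d = json.loads(payload)
        return cls(
            atoms=[AtomRecord(**a) for a in d["atoms"]],
            bonds=[BondRecord(tuple(b["endpoints"]), b["order"]) for b in d["bonds"]],
            name=d.get("name"),
            source_smiles=d.get("source_smiles"),
            flags=frozenset(d.get("flags", [])),
        )


@dataclass
class AtomFeatureMatrix:
    values: np.ndarray  # (n_atoms, n_features)
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match matrix width")


# ---------------------------------------------------------------------------
# RDKit bridging
# ---------------------------------------------------------------------------

def _canonical_order(mol: Chem.Mol) -> list[int]:
    """Permutation `order` such that mol atom order[k] becomes new atom k.

    Ranks ignore chirality so enantiomers receive identical orderings.
    """
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True, includeChirality=False))
    order = [0] * len(ranks)
    for old_idx, rank in enumerate(ranks):
        order[rank] = old_idx
    return order


def graph_from_rdkit(
    mol: Chem.Mol,
    include_chirality: bool = True,
    name: str | None = None,
    source_smiles: str | None = None,
) -> tuple[MolecularGraph, list[int]]:
    """Build a canonical-order graph; also return the old->new atom order.

    ``order[k]`` is the index in ``mol`` of the atom that becomes atom ``k``
    of the returned graph — use it to permute per-atom data (coordinates).
    """
    order = _canonical_order(mol)
    mol = Chem.RenumberAtoms(mol, order)
    atoms = []
    for a in mol.GetAtoms():
        tag = _RD_CHI_TO_TAG.get(a.GetChiralTag(), "none") if include_chirality else "none"
        atoms.append(
            AtomRecord(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                degree=a.GetDegree(),
                aromatic=a.GetIsAromatic(),
                n_hydrogens=a.GetTotalNumHs(),
                chiral_tag=tag,
            )
        )
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append(BondRecord((min(i, j), max(i, j)), _RD_BOND_TO_ORDER[b.GetBondType()]))
    bonds.sort(key=lambda b: b.endpoints)
    return MolecularGraph(atoms, bonds, name=name, source_smiles=source_smiles), order


def graph_to_rdkit(graph: MolecularGraph) -> Chem.Mol:
    """Rebuild a sanitized RDKit molecule from a graph (inverse of parsing)."""
    rw = Chem.RWMol()
    for a in graph.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.formal_charge)
        atom.SetChiralTag(_TAG_TO_RD_CHI[a.chiral_tag])
        atom.SetNumExplicitHs(a.n_hydrogens)
        atom.SetNoImplicit(True)
        atom.SetIsAromatic(a.aromatic)
        rw.AddAtom(atom)
    for b in graph.bonds:
        i, j = b.endpoints
        rw.AddBond(i, j, _ORDER_TO_RD_BOND[b.order])
        if b.order == "aromatic":
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def canonical_key(graph: MolecularGraph) -> str:
    """Canonical SMILES of the graph, used to group identical structures."""
    return Chem.MolToSmiles(graph_to_rdkit(graph))


def parse_smiles(smiles: str, include_chirality: bool = True) -> MolecularGraph:
    """Parse a SMILES string into a canonical-order MolecularGraph."""
    if not smiles:
        raise MolParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MolParseError(f"could not parse SMILES {smiles!r}")
    graph, _ = graph_from_rdkit(mol, include_chirality, source_smiles=smiles)
    return graph


# ---------------------------------------------------------------------------
# 3D structure loading
# ---------------------------------------------------------------------------

def _structure_from_rdkit_3d(
    mol: Chem.Mol, name: str | None
) -> tuple[MolecularGraph, np.ndarray]:
    """Heavy-atom graph + aligned coordinates from an RDKit mol with a conformer."""
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    graph, order = graph_from_rdkit(mol, include_chirality=True, name=name)
    return graph, coords[order]


def _load_sdf(path: Path) -> tuple[list, list]:
    entries, rejects = [], []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            rejects.append((f"record {i}", "parse or sanitization failure"))
            continue
        try:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record {i}"
            entries.append(_structure_from_rdkit_3d(mol, name or f"record {i}"))
        except Exception as exc:  # conformer missing, valence issues, ...
            rejects.append((f"record {i}", str(exc)))
    return entries, rejects


def _load_cif(path: Path) -> tuple[list, list]:
    """Read a small-molecule CIF; bonds are perceived from the coordinates."""
    small = gemmi.read_small_structure(str(path))
    if not small.sites:
        return [], [(path.name, "no atom sites")]
    cell = small.cell
    rw = Chem.RWMol()
    conf_pos = []
    for site in small.sites:
        pos = cell.orthogonalize(site.fract)
        rw.AddAtom(Chem.Atom(site.element.name))
        conf_pos.append((pos.x, pos.y, pos.z))
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(conf_pos):
        conf.SetAtomPosition(i, xyz)
    mol.AddConformer(conf)
    try:
        rdDetermineBonds.DetermineBonds(mol, charge=0)
    except Exception as exc:
        return [], [(small.name or path.name, f"ambiguous bonding: {exc}")]
    return [_structure_from_rdkit_3d(mol, small.name or path.stem)], []


def load_structures(
    path: str | Path, format: str
) -> tuple[list[tuple[MolecularGraph, np.ndarray]], list[tuple[str, str]]]:
    """Load (graph, coordinates) pairs from an SDF or small-molecule CIF file.

    Returns ``(entries, rejects)`` where rejects are ``(record id, reason)``
    pairs for records that failed parsing or bond perception.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "sdf":
        entries, rejects = _load_sdf(path)
    elif format == "cif":
        entries, rejects = _load_cif(path)
    else:
        raise ValueError(f"unknown structure format {format!r}")
    if not entries:
        raise MolParseError(f"no valid records in {path} (rejects: {rejects})")
    return entries, rejects


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def feature_names(vocabulary: Sequence[str] = DEFAULT_VOCABULARY) -> list[str]:
    names = [f"element={e}" for e in vocabulary]
    names += ["formal_charge", "degree", "aromatic", "n_hydrogens"]
    names += [f"chiral={t}" for t in CHIRAL_TAGS]
    return names


def n_features(vocabulary: Sequence[str] = DEFAULT_VOCABULARY) -> int:
    return len(vocabulary) + 4 + len(CHIRAL_TAGS)


def featurize_atoms(
    graph: MolecularGraph, vocabulary: Sequence[str] = DEFAULT_VOCABULARY
) -> AtomFeatureMatrix:
    """Fixed-width per-atom features: one-hot element, charge, degree,
    aromaticity, H-count, one-hot chiral tag."""
    vocab_idx = {e: k for k, e in enumerate(vocabulary)}
    rows = np.zeros((graph.n_atoms, n_features(vocabulary)), dtype=float)
    off = len(vocabulary)
    for i, a in enumerate(graph.atoms):
        if a.element not in vocab_idx:
            raise VocabularyError(
                f"element {a.element!r} (atom {i}) not in feature vocabulary"
            )
        rows[i, vocab_idx[a.element]] = 1.0
        rows[i, off + 0] = a.formal_charge
        rows[i, off + 1] = a.degree
        rows[i, off + 2] = 1.0 if a.aromatic else 0.0
        rows[i, off + 3] = a.n_hydrogens
        rows[i, off + 4 + CHIRAL_TAGS.index(a.chiral_tag)] = 1.0
    return AtomFeatureMatrix(rows, feature_names(vocabulary))


def strip_chirality(graph: MolecularGraph) -> MolecularGraph:
    """Copy of the graph with all chiral tags reset to "none"."""
    atoms = [
        AtomRecord(a.element, a.formal_charge, a.degree, a.aromatic, a.n_hydrogens, "none")
        for a in graph.atoms
    ]
    return MolecularGraph(atoms, list(graph.bonds), graph.name, graph.source_smiles, graph.flags)
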