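import pytest

from molfoundry import BackboneConfig, FixtureConfig, generate_molecule_set, init_backbone
from molfoundry.graphs import BondRecord, MolecularGraph


@pytest.fixture(scope="session")
def molset():
    """20 deterministic fixture molecules with relaxed conformers."""
    return generate_molecule_set(FixtureConfig(n_molecules=20, seed=5))


@pytest.fixture(scope="session")
def tiny_config():
    return BackboneConfig(hidden_dim=16, message_steps=2, readout_dim=12, seed=0)


@pytest.fixture(scope="session")
def tiny_backbone(tiny_config):
    return init_backbone(tiny_config)


def permute_graph(graph: MolecularGraph, perm) -> MolecularGraph:
    """Relabel atoms by a permutation: new index perm[i] holds old atom i."""
    n = graph.n_atoms
    atoms = [None] * n
    for old, new in enumerate(perm):
        atoms[new] = graph.atoms[old]
    bonds = []
    for b in graph.bonds:
        i, j = perm[b.endpoints[0]], perm[b.endpoints[1]]
        bonds.append(BondRecord((min(i, j), max(i, j)), b.order))
    return MolecularGraph(list(atoms), bonds, name=graph.name)


def disjoint_union(graph: MolecularGraph) -> MolecularGraph:
    """Two disconnected copies of a molecule in one graph."""
    n = graph.n_atoms
    atoms = list(graph.atoms) + list(graph.atoms)
    bonds = list(graph.bonds) + [
        BondRecord((b.endpoints[0] + n, b.endpoints[1] + n), b.order) for b in graph.bonds
    ]
    return MolecularGraph(atoms, bonds)
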