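import random

import networkx as nx
import pytest

from proximal.chem_io import Atom, Bond, MolecularGraph

MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


def random_molecule(rng: random.Random, n: int) -> MolecularGraph | None:
    """Small random connected C/N/O molecule with valence-legal single bonds.

    Returns None when the draw cannot be completed (caller resamples).
    """
    elements = [rng.choice("CCCNO") for _ in range(n)]
    atoms = [Atom(i + 1, elements[i]) for i in range(n)]
    bonds = []
    deg = [0] * (n + 1)
    for i in range(2, n + 1):
        cands = [j for j in range(1, i) if deg[j] < MAX_VALENCE[elements[j - 1]]]
        if not cands:
            return None
        j = rng.choice(cands)
        bonds.append(Bond(i, j))
        deg[i] += 1
        deg[j] += 1
    for _ in range(rng.randrange(0, 2)):
        i, j = rng.randrange(1, n + 1), rng.randrange(1, n + 1)
        if i == j or any(b.key() == (min(i, j), max(i, j)) for b in bonds):
            continue
        if deg[i] < MAX_VALENCE[elements[i - 1]] and deg[j] < MAX_VALENCE[elements[j - 1]]:
            bonds.append(Bond(i, j))
            deg[i] += 1
            deg[j] += 1
    try:
        g = MolecularGraph(atoms, bonds)
        g.to_rdkit(sanitize=True)
    except Exception:
        return None
    return g


def sample_molecule(rng: random.Random, lo: int = 3, hi: int = 9) -> MolecularGraph:
    while True:
        g = random_molecule(rng, rng.randrange(lo, hi + 1))
        if g is not None:
            return g


def permute_graph(g: MolecularGraph, rng: random.Random) -> MolecularGraph:
    """Isomorphic copy with shuffled atom order."""
    perm = list(range(1, g.n_atoms + 1))
    rng.shuffle(perm)
    relabel = {old: new for new, old in enumerate(perm, start=1)}
    atoms = [None] * g.n_atoms
    for a in g.atoms:
        atoms[relabel[a.index] - 1] = Atom(
            relabel[a.index], a.element, a.formal_charge, a.implicit_h, a.aromatic
        )
    bonds = [Bond(relabel[b.i], relabel[b.j], b.order, b.aromatic) for b in g.bonds]
    return MolecularGraph(atoms, bonds, name=g.name)


def graphs_isomorphic(g1: MolecularGraph, g2: MolecularGraph) -> bool:
    """Brute-force isomorphism oracle (networkx VF2), independent of RDKit."""

    def to_nx(g):
        G = nx.Graph()
        for a in g.atoms:
            G.add_node(a.index, label=(a.element, a.formal_charge))
        for b in g.bonds:
            G.add_edge(b.i, b.j, label="ar" if b.aromatic else b.order)
        return G

    return nx.is_isomorphic(
        to_nx(g1),
        to_nx(g2),
        node_match=lambda a, b: a["label"] == b["label"],
        edge_match=lambda a, b: a["label"] == b["label"],
    )


@pytest.fixture(scope="session")
def curated_build():
    from proximal.fixtures import curated_tables

    return curated_tables()


@pytest.fixture(scope="session")
def bpa():
    from proximal.fixtures import fixture_graph

    return fixture_graph("bisphenol_a")


@pytest.fixture(scope="session")
def pcb3():
    from proximal.fixtures import fixture_graph

    return fixture_graph("chlorobiphenyl")


@pytest.fixture(scope="session")
def acetaminophen():
    from proximal.fixtures import fixture_graph

    return fixture_graph("acetaminophen")
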