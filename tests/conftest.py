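"""Shared fixtures: random molecular graphs and study molecules."""

from __future__ import annotations

import random

import networkx as nx
import pytest

from permqspr.graph import Atom, Bond, MolecularGraph


def random_graph(rng: random.Random, max_atoms: int = 12, hetero: bool = True) -> MolecularGraph:
    """Random connected graph: a random tree plus a few cycle-closing
    edges, with ring membership derived from the bridge structure."""
    n = rng.randint(2, max_atoms)
    edges = [(rng.randrange(i), i) for i in range(1, n)]  # random tree
    extra = rng.randint(0, min(2, n * (n - 1) // 2 - (n - 1)))
    existing = {frozenset(e) for e in edges}
    attempts = 0
    while extra > 0 and attempts < 50:
        i, j = rng.randrange(n), rng.randrange(n)
        attempts += 1
        if i != j and frozenset((i, j)) not in existing:
            edges.append((i, j))
            existing.add(frozenset((i, j)))
            extra -= 1
    nxg = nx.Graph(edges)
    bridges = {frozenset(e) for e in nx.bridges(nxg)}
    atoms = []
    for _ in range(n):
        if hetero and rng.random() < 0.3:
            el = rng.choice(["N", "O", "S", "Cl"])
        else:
            el = "C"
        atoms.append(Atom(el, rng.randint(0, 2)))
    bonds = []
    for i, j in edges:
        in_ring = frozenset((i, j)) not in bridges
        order = rng.choice([1, 1, 1, 2]) if not in_ring else rng.choice([1, 1, 2])
        bonds.append(Bond(i, j, order, in_ring))
    return MolecularGraph(atoms=atoms, bonds=bonds)


@pytest.fixture
def graph_factory():
    return random_graph


@pytest.fixture(scope="session")
def study_molecules():
    from permqspr.synth import fixture_molecules

    return fixture_molecules()
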