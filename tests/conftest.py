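"""Shared fixtures: the small-graph catalog and random-graph helpers."""

from __future__ import annotations

import random

import networkx as nx
import pytest


def barbell_triangles() -> nx.Graph:
    """Two triangles joined by a single bridge edge."""
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


def two_disjoint_k3() -> nx.Graph:
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


#: name -> constructor for the fixed catalog used in oracle-equivalence and
#: closed-form tests (paths, star, cliques, cycle, barbell).
CATALOG = {
    "P2": lambda: nx.path_graph(2),
    "P3": lambda: nx.path_graph(3),
    "P4": lambda: nx.path_graph(4),
    "P5": lambda: nx.path_graph(5),
    "S4": lambda: nx.star_graph(3),       # 4 nodes: center 0 + 3 leaves
    "K3": lambda: nx.complete_graph(3),
    "K4": lambda: nx.complete_graph(4),
    "K5": lambda: nx.complete_graph(5),
    "C4": lambda: nx.cycle_graph(4),
    "barbell": barbell_triangles,
}


def random_small_graphs(n_graphs: int, max_nodes: int = 7,
                        seed: int = 20240) -> list[nx.Graph]:
    """Seeded random graphs (possibly disconnected, never empty)."""
    rng = random.Random(seed)
    out = []
    while len(out) < n_graphs:
        n = rng.randint(2, max_nodes)
        g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.9),
                                seed=rng.randrange(2 ** 30))
        out.append(g)
    return out


@pytest.fixture(scope="session")
def catalog() -> dict[str, nx.Graph]:
    return {name: make() for name, make in CATALOG.items()}


@pytest.fixture(scope="session")
def small_random_graphs() -> list[nx.Graph]:
    return random_small_graphs(50)
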