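"""Centrality indices: frozen fixtures, oracle equivalence, invariants."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from hubnet import centrality as ct
from hubnet import oracle as orc
from .conftest import random_small_graphs

DETERMINISTIC = orc.ORACLE_INDICES  # everything except epc


# ---------------------------------------------------------------------------
# frozen per-index examples (graph name from the catalog, node, expected)

EXAMPLES = [
    ("degree", "S4", 0, 3.0),
    ("degree", "K4", 1, 3.0),
    ("clustering_coefficient", "K3", 0, 1.0),
    ("clustering_coefficient", "S4", 0, 0.0),
    ("betweenness", "K5", 0, 0.0),
    ("betweenness", "P4", 1, 2.0),          # pairs (0,2), (0,3)
    ("betweenness", "C4", 0, 0.5),          # one pair, two equal geodesics
    ("stress", "P4", 1, 2.0),
    ("stress", "K5", 0, 0.0),
    ("stress", "C4", 0, 1.0),
    ("closeness", "S4", 0, 3.0),
    ("closeness", "S4", 1, 2.0),            # 1 + 1/2 + 1/2
    ("radiality", "S4", 0, 2.0),            # 3*(2+1-1)/3
    ("radiality", "S4", 1, 4.0 / 3.0),
    ("radiality", "K4", 0, 1.0),
    ("eccentricity", "K4", 0, 1.0),
    ("eccentricity", "P3", 1, 1.0),
    ("eccentricity", "P3", 0, 0.5),
    ("bottleneck", "S4", 0, 3.0),
    ("bottleneck", "S4", 1, 0.0),
    ("bottleneck", "P2", 0, 1.0),           # subtree 1 > 2/4; oracle-decided
    ("mnc", "K5", 0, 4.0),
    ("mnc", "S4", 0, 1.0),
    ("dmnc", "S4", 0, 0.0),
    ("dmnc", "K5", 0, 6.0 / 4.0 ** 1.7),
    ("dmnc", "K3", 0, 1.0 / 2.0 ** 1.7),
    ("mcc", "K3", 0, 2.0),                  # (3-1)!
    ("mcc", "K4", 0, 6.0),                  # (4-1)!
    ("mcc", "S4", 0, 3.0),                  # edgeless neighborhood -> degree
]


@pytest.mark.parametrize("index_name,graph_name,node,expected", EXAMPLES)
def test_index_fixture(catalog, index_name, graph_name, node, expected):
    scores = ct._DETERMINISTIC[index_name](catalog[graph_name])
    assert scores[node] == pytest.approx(expected, abs=1e-9)


def test_isolated_node_scores():
    g = nx.Graph()
    g.add_node("X")
    assert ct.degree(g)["X"] == 0.0
    assert ct.closeness(g)["X"] == 0.0
    assert ct.eccentricity(g)["X"] == 0.0
    assert ct.mnc(g)["X"] == 0.0
    assert ct.mcc(g)["X"] == 0.0


def test_mnc_of_p2_plus_isolated_neighbor():
    """Node whose neighbors form an edge plus an isolated vertex -> MNC 2."""
    g = nx.Graph([("v", "a"), ("v", "b"), ("v", "c"), ("a", "b")])
    assert ct.mnc(g)["v"] == 2.0


def test_clustering_one_of_three_neighbor_pairs():
    g = nx.Graph([("v", "a"), ("v", "b"), ("v", "c"), ("a", "b")])
    assert ct.clustering_coefficient(g)["v"] == pytest.approx(1 / 3)


# ---------------------------------------------------------------------------
# oracle equivalence (catalog + seeded random graphs)

@pytest.mark.parametrize("index_name", DETERMINISTIC)
def test_oracle_equivalence_on_catalog(catalog, index_name):
    for name, g in catalog.items():
        fast = ct._DETERMINISTIC[index_name](g)
        slow = orc.brute_force_oracle(g, index_name)
        for v in g:
            assert fast[v] == pytest.approx(slow[v], abs=1e-9), (name, v)


@pytest.mark.parametrize("index_name", DETERMINISTIC)
def test_oracle_equivalence_on_random_graphs(small_random_graphs, index_name):
    for i, g in enumerate(small_random_graphs):
        fast = ct._DETERMINISTIC[index_name](g)
        slow = orc.brute_force_oracle(g, index_name)
        for v in g:
            assert fast[v] == pytest.approx(slow[v], abs=1e-9), \
                (i, v, sorted(g.edges()))


def test_oracle_refuses_large_graphs():
    with pytest.raises(ValueError):
        orc.brute_force_oracle(nx.path_graph(11), "degree")


# ---------------------------------------------------------------------------
# EPC: trivial limits, exact expectation, reproducibility, 1/K variance

def test_epc_retain_all_is_one():
    g = nx.path_graph(5)
    assert all(x == pytest.approx(1.0)
               for x in ct.epc(g, trials=10, retain_p=1.0, seed=0).values())

def test_epc_retain_none_is_reciprocal_n():
    g = nx.path_graph(4)
    assert all(x == pytest.approx(0.25)
               for x in ct.epc(g, trials=10, retain_p=0.0, seed=0).values())

def test_epc_matches_exact_expectation_on_k2_and_k3():
    k2 = nx.complete_graph(2)
    est = ct.epc(k2, trials=20000, retain_p=0.5, seed=1)
    assert est[0] == pytest.approx(0.75, abs=0.01)
    k3 = nx.complete_graph(3)
    exact = orc.epc_exact(k3, retain_p=0.5)
    est = ct.epc(k3, trials=20000, retain_p=0.5, seed=1)
    for v in k3:
        assert est[v] == pytest.approx(exact[v], abs=0.01)

def test_epc_seed_reproducibility():
    g = nx.gnp_random_graph(10, 0.4, seed=3)
    a = ct.epc(g, trials=200, retain_p=0.5, seed=42)
    b = ct.epc(g, trials=200, retain_p=0.5, seed=42)
    assert a == b

def test_epc_variance_shrinks_as_one_over_k():
    """Monte Carlo variance at K=10000 should be ~100x below K=100."""
    g = nx.gnp_random_graph(8, 0.35, seed=5)
    v = sorted(g.nodes())[0]
    est100 = [ct.epc(g, trials=100, retain_p=0.5, seed=s)[v]
              for s in range(25)]
    est10k = [ct.epc(g, trials=10000, retain_p=0.5, seed=s)[v]
              for s in range(25)]
    assert np.var(est10k) < np.var(est100) / 20


# ---------------------------------------------------------------------------
# invariants

def test_integer_valued_indices_and_ranges(small_random_graphs):
    for g in small_random_graphs[:20]:
        n = g.number_of_nodes()
        for name in ("degree", "stress", "bottleneck", "mnc", "mcc"):
            for x in ct._DETERMINISTIC[name](g).values():
                assert x >= 0 and x == pytest.approx(round(x), abs=1e-9), name
        assert all(x <= n - 1 + 1e-9 for x in ct.closeness(g).values())
        for name in ("eccentricity", "clustering_coefficient"):
            assert all(-1e-12 <= x <= 1 + 1e-12
                       for x in ct._DETERMINISTIC[name](g).values()), name
        e = ct.epc(g, trials=50, retain_p=0.5, seed=0)
        assert all(0 < x <= 1 for x in e.values())


@pytest.mark.parametrize("index_name",
                         [n for n in DETERMINISTIC if n != "bottleneck"])
def test_label_invariance_under_permutation(index_name):
    """Permuting node labels permutes scores identically."""
    for g in random_small_graphs(8, seed=777):
        perm = {v: f"Z{(v * 7 + 3) % 100:02d}" for v in g}
        h = nx.relabel_nodes(g, perm)
        orig = ct._DETERMINISTIC[index_name](g)
        relab = ct._DETERMINISTIC[index_name](h)
        for v in g:
            assert relab[perm[v]] == pytest.approx(orig[v], abs=1e-9)


def test_bottleneck_invariant_under_order_preserving_relabeling():
    """Bottleneck's smallest-label parent tie-break commutes with any
    order-preserving relabeling."""
    for g in random_small_graphs(8, seed=778):
        perm = {v: f"N{v:03d}" for v in sorted(g.nodes())}  # keeps order
        h = nx.relabel_nodes(g, perm)
        orig = ct.bottleneck(g)
        relab = ct.bottleneck(h)
        for v in g:
            assert relab[perm[v]] == orig[v]


def test_disconnected_graph_all_indices_finite():
    g = nx.disjoint_union(nx.path_graph(3), nx.complete_graph(4))
    g.add_node(99)
    frame = ct.compute_indices(g, seed=0, epc_trials=50)
    assert frame.shape == (8, len(ct.INDEX_NAMES))
    assert np.isfinite(frame.to_numpy()).all()
    assert (frame.to_numpy() >= 0).all()


def test_compute_indices_rejects_unknown_name():
    with pytest.raises(ValueError):
        ct.compute_indices(nx.path_graph(3), indices=("pagerank",))
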