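"""Hub-node centrality indices for protein-interaction networks.

Twelve per-node indices are provided, covering the cytoHubba family used in
hub-gene prioritization:

========================  ============================================================
index                     definition (higher = more central throughout)
========================  ============================================================
degree                    number of immediate neighbors
clustering_coefficient    edge density among a node's neighbors
betweenness               sum over unordered pairs of the geodesic fraction through v
stress                    raw count of geodesics through v
closeness                 harmonic closeness, sum of reciprocal distances
radiality                 diameter-shifted mean closeness, sum(D+1-d)/(n_c-1)
eccentricity              reciprocal graph eccentricity, 1/max_w d(v,w)
bottleneck                number of BFS shortest-path trees in which v's subtree
                          exceeds a quarter of the tree
epc                       edge-percolated component: mean reachable fraction under
                          Bernoulli(p) edge retention (Monte Carlo, K trials)
mnc                       size of the largest component induced by v's neighbors
dmnc                      edge count of that component divided by its size^1.7
mcc                       maximal clique centrality, sum of (|C|-1)! over maximal
                          cliques containing v (degree when the neighborhood has
                          no edge)
========================  ============================================================

Distance-based indices on a disconnected graph are computed per connected
component; unreachable pairs contribute nothing.  All functions return a
plain ``dict`` node -> float covering every node of the graph.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Callable, Iterable, Optional

import networkx as nx
import numpy as np

INDEX_NAMES = (
    "degree", "betweenness", "closeness", "bottleneck", "radiality",
    "stress", "clustering_coefficient", "eccentricity", "epc", "dmnc",
    "mnc", "mcc",
)

#: Table-1 column order used by report rendering.
INFORMATIVE_ORDER = (
    "degree", "betweenness", "closeness", "radiality", "stress", "epc",
    "dmnc", "clustering_coefficient",
)


def degree(g: nx.Graph) -> dict:
    return {v: float(d) for v, d in g.degree()}


def clustering_coefficient(g: nx.Graph) -> dict:
    return {v: float(c) for v, c in nx.clustering(g).items()}


def betweenness(g: nx.Graph) -> dict:
    """Unnormalized shortest-path betweenness, each unordered pair once."""
    return {v: float(b) for v, b in
            nx.betweenness_centrality(g, normalized=False).items()}


def closeness(g: nx.Graph) -> dict:
    """Harmonic closeness: sum of 1/d(v,w); unreachable pairs contribute 0."""
    return {v: float(c) for v, c in nx.harmonic_centrality(g).items()}


def _bfs_sigma(g: nx.Graph, s) -> tuple[dict, dict, list, dict]:
    """Single-source BFS returning distances, geodesic counts, visit order,
    and shortest-path predecessor lists (Brandes-style)."""
    dist = {s: 0}
    sigma = {s: 1.0}
    preds: dict = {s: []}
    order = [s]
    q = deque([s])
    while q:
        u = q.popleft()
        for w in g[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0.0
                preds[w] = []
                order.append(w)
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
                preds[w].append(u)
    return dist, sigma, order, preds


def stress(g: nx.Graph) -> dict:
    """Stress centrality: the number of geodesics passing through each node
    (endpoints excluded), each unordered pair counted once.

    Uses a Brandes-style accumulation: with tau_s(v) = number of geodesic
    continuations from v away from source s, the per-source contribution is
    sigma_sv * tau_s(v), and the undirected total double-counts each pair.
    """
    scores = {v: 0.0 for v in g}
    for s in g:
        dist, sigma, order, preds = _bfs_sigma(g, s)
        tau = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                tau[v] += tau[w] + 1.0
        for v in order:
            if v != s:
                scores[v] += sigma[v] * tau[v]
    return {v: x / 2.0 for v, x in scores.items()}


def _component_distances(g: nx.Graph):
    """Yield (component nodes, dist dict-of-dicts) per connected component."""
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        yield comp, dist


def radiality(g: nx.Graph) -> dict:
    """Radiality: sum over reachable w of (diameter + 1 - d(v,w)), divided by
    (component size - 1).  Isolated nodes score 0."""
    scores: dict = {}
    for comp, dist in _component_distances(g):
        nc = len(comp)
        if nc == 1:
            scores[next(iter(comp))] = 0.0
            continue
        diam = max(d for row in dist.values() for d in row.values())
        for v in comp:
            total = sum(diam + 1 - d for w, d in dist[v].items() if w != v)
            scores[v] = total / (nc - 1)
    return scores


def eccentricity(g: nx.Graph) -> dict:
    """Reciprocal eccentricity within each component (singletons score 0)."""
    scores: dict = {}
    for comp, dist in _component_distances(g):
        for v in comp:
            ecc = max(dist[v].values())
            scores[v] = 1.0 / ecc if ecc > 0 else 0.0
    return scores


def bottleneck(g: nx.Graph) -> dict:
    """Bottleneck centrality.

    For every root s a deterministic BFS shortest-path tree is built over
    s's component, each node's parent being its smallest-label neighbor one
    step closer to s.  A node v scores one point per root s != v for which
    v's subtree (v included) holds strictly more than a quarter of the
    tree's nodes.
    """
    scores = {v: 0.0 for v in g}
    for s in g:
        dist, _, order, _ = _bfs_sigma(g, s)
        parent = {}
        for v in order:
            if v == s:
                continue
            parent[v] = min(w for w in g[v] if dist[w] == dist[v] - 1)
        subtree = {v: 1 for v in order}
        for v in reversed(order):
            if v != s:
                subtree[parent[v]] += subtree[v]
        quarter = len(order) / 4.0
        for v in order:
            if v != s and subtree[v] > quarter:
                scores[v] += 1.0
    return scores


def epc(g: nx.Graph, trials: int = 1000, retain_p: float = 0.5,
        seed: Optional[int] = None) -> dict:
    """Edge-percolated component (Monte Carlo).

    In each of *trials* rounds every edge is kept independently with
    probability *retain_p*; a node's score is the mean over rounds of the
    fraction of the graph it can still reach (itself included).

    Deterministic for a fixed seed and graph; scores lie in (0, 1].
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0.0 <= retain_p <= 1.0:
        raise ValueError("retain_p must be in [0, 1]")
    nodes = sorted(g.nodes())
    n = len(nodes)
    if n == 0:
        return {}
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array([[idx[u], idx[v]] for u, v in
                      sorted(tuple(sorted(e)) for e in g.edges())],
                     dtype=np.int64)
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    parent = np.empty(n, dtype=np.int64)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    for _ in range(trials):
        parent[:] = np.arange(n)
        if len(edges):
            keep = rng.random(len(edges)) < retain_p
            for u, v in edges[keep]:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[rv] = ru
        roots = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
        _, inverse, counts = np.unique(roots, return_inverse=True,
                                       return_counts=True)
        acc += counts[inverse] / n
    acc /= trials
    return {v: float(acc[idx[v]]) for v in nodes}


def _max_neighborhood_component(g: nx.Graph, v) -> nx.Graph:
    nbrs = list(g[v])
    if not nbrs:
        return nx.Graph()
    sub = g.subgraph(nbrs)
    comp = max(nx.connected_components(sub), key=lambda c: (len(c), min(c)))
    return sub.subgraph(comp)


def mnc(g: nx.Graph) -> dict:
    """Maximum neighborhood component: size of the largest connected
    component of the neighbor-induced subgraph (0 for isolated nodes)."""
    return {v: float(_max_neighborhood_component(g, v).number_of_nodes())
            for v in g}


def dmnc(g: nx.Graph, epsilon: float = 1.7) -> dict:
    """Density of the maximum neighborhood component: |E(M)| / |V(M)|^eps,
    0 when the neighborhood contains no edge."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    scores = {}
    for v in g:
        m_sub = _max_neighborhood_component(g, v)
        e = m_sub.number_of_edges()
        scores[v] = e / m_sub.number_of_nodes() ** epsilon if e else 0.0
    return scores


def mcc(g: nx.Graph) -> dict:
    """Maximal clique centrality: sum of (|C|-1)! over maximal cliques C
    containing v; equals the degree when v's neighborhood is edgeless
    (every maximal clique through v is then a single edge)."""
    scores = {v: 0.0 for v in g}
    for clique in nx.find_cliques(g):
        w = float(math.factorial(len(clique) - 1))
        for v in clique:
            scores[v] += w
    for v in g:  # isolated nodes sit in the trivial clique {v}
        if g.degree(v) == 0:
            scores[v] = 0.0
    return scores


_DETERMINISTIC: dict[str, Callable[[nx.Graph], dict]] = {
    "degree": degree,
    "clustering_coefficient": clustering_coefficient,
    "betweenness": betweenness,
    "stress": stress,
    "closeness": closeness,
    "radiality": radiality,
    "eccentricity": eccentricity,
    "bottleneck": bottleneck,
    "mnc": mnc,
    "dmnc": dmnc,
    "mcc": mcc,
}


def compute_indices(g: nx.Graph, indices: Iterable[str] = INDEX_NAMES,
                    epc_trials: int = 1000, epc_p: float = 0.5,
                    seed: Optional[int] = None):
    """Compute the requested indices; returns a pandas DataFrame indexed by
    node with one column per index (column order as requested)."""
    import pandas as pd

    names = list(indices)
    unknown = [x for x in names if x not in INDEX_NAMES]
    if unknown:
        raise ValueError(f"unknown centrality indices: {unknown}")
    nodes = sorted(g.nodes())
    data = {}
    for name in names:
        if name == "epc":
            data[name] = epc(g, trials=epc_trials, retain_p=epc_p, seed=seed)
        else:
            data[name] = _DETERMINISTIC[name](g)
    return pd.DataFrame({name: [data[name][v] for v in nodes]
                         for name in names}, index=pd.Index(nodes, name="node"))
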