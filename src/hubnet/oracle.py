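"""Brute-force centrality oracles for tiny graphs.

Every function here recomputes an index by exhaustive enumeration —
all simple paths for the geodesic indices, all node subsets for cliques,
all 2^m edge subsets for the exact percolation expectation — sharing no
machinery with :mod:`hubnet.centrality`.  They are the arbiters in
equivalence tests and are refused above 10 nodes.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations
from typing import Optional

import networkx as nx

MAX_NODES = 10
_EPC_MAX_EDGES = 15

ORACLE_INDICES = (
    "degree", "betweenness", "closeness", "bottleneck", "radiality",
    "stress", "clustering_coefficient", "eccentricity", "dmnc", "mnc", "mcc",
)


def _check(g: nx.Graph) -> None:
    if g.number_of_nodes() > MAX_NODES:
        raise ValueError(
            f"oracle refuses graphs with more than {MAX_NODES} nodes")


def _all_simple_paths(g: nx.Graph, s, t) -> list[tuple]:
    """Every simple s-t path, found by explicit DFS over permutative
    extension (no networkx shortest-path machinery)."""
    paths = []

    def extend(path: list) -> None:
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for w in g[u]:
            if w not in path:
                path.append(w)
                extend(path)
                path.pop()

    extend([s])
    return paths


def _geodesics(g: nx.Graph):
    """dist[(s,t)] and the list of geodesics per ordered pair (via
    exhaustive simple-path enumeration); unreachable pairs absent."""
    dist: dict = {}
    geo: dict = {}
    for s, t in permutations(g.nodes(), 2):
        paths = _all_simple_paths(g, s, t)
        if not paths:
            continue
        d = min(len(p) - 1 for p in paths)
        dist[(s, t)] = d
        geo[(s, t)] = [p for p in paths if len(p) - 1 == d]
    return dist, geo


def degree(g: nx.Graph) -> dict:
    _check(g)
    return {v: float(sum(1 for _ in g[v])) for v in g}


def clustering_coefficient(g: nx.Graph) -> dict:
    _check(g)
    out = {}
    for v in g:
        nbrs = list(g[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        e = sum(1 for a, b in combinations(nbrs, 2) if g.has_edge(a, b))
        out[v] = 2.0 * e / (k * (k - 1))
    return out


def betweenness(g: nx.Graph) -> dict:
    _check(g)
    dist, geo = _geodesics(g)
    out = {v: 0.0 for v in g}
    for s, t in combinations(g.nodes(), 2):
        if (s, t) not in geo:
            continue
        paths = geo[(s, t)]
        for v in g:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


def stress(g: nx.Graph) -> dict:
    _check(g)
    _, geo = _geodesics(g)
    out = {v: 0.0 for v in g}
    for s, t in combinations(g.nodes(), 2):
        if (s, t) not in geo:
            continue
        for v in g:
            if v in (s, t):
                continue
            out[v] += sum(1 for p in geo[(s, t)] if v in p)
    return out


def closeness(g: nx.Graph) -> dict:
    _check(g)
    dist, _ = _geodesics(g)
    return {v: sum(1.0 / d for (s, _t), d in dist.items() if s == v)
            for v in g}


def radiality(g: nx.Graph) -> dict:
    _check(g)
    dist, _ = _geodesics(g)
    out = {}
    for v in g:
        reach = {t: d for (s, t), d in dist.items() if s == v}
        if not reach:
            out[v] = 0.0
            continue
        comp = set(reach) | {v}
        diam = max(d for (s, t), d in dist.items()
                   if s in comp and t in comp)
        out[v] = sum(diam + 1 - d for d in reach.values()) / (len(comp) - 1)
    return out


def eccentricity(g: nx.Graph) -> dict:
    _check(g)
    dist, _ = _geodesics(g)
    out = {}
    for v in g:
        ds = [d for (s, _t), d in dist.items() if s == v]
        out[v] = 1.0 / max(ds) if ds else 0.0
    return out


def bottleneck(g: nx.Graph) -> dict:
    """Stated-rule reimplementation: smallest-label-parent shortest-path
    tree per root, subtree sizes counted by walking every node's parent
    chain (distances from exhaustive path enumeration)."""
    _check(g)
    dist, _ = _geodesics(g)
    out = {v: 0.0 for v in g}
    for s in g:
        comp = [v for v in g if v == s or (s, v) in dist]
        parent = {}
        for v in comp:
            if v == s:
                continue
            dv = dist[(s, v)]
            parent[v] = min(w for w in g[v]
                            if (w == s and dv == 1)
                            or (s, w) in dist and dist[(s, w)] == dv - 1)
        for v in comp:
            if v == s:
                continue
            size = 0
            for w in comp:  # w's chain to the root passes through v?
                u = w
                while True:
                    if u == v:
                        size += 1
                        break
                    if u == s:
                        break
                    u = parent[u]
            if size > len(comp) / 4.0:
                out[v] += 1.0
    return out


def _reachable(nodes: list, edges: set, v) -> set:
    """Transitive closure from v using repeated sweeps over the edge set."""
    reach = {v}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            if a in reach and b not in reach:
                reach.add(b)
                changed = True
            elif b in reach and a not in reach:
                reach.add(a)
                changed = True
    return reach


def mnc(g: nx.Graph) -> dict:
    _check(g)
    out = {}
    for v in g:
        nbrs = list(g[v])
        if not nbrs:
            out[v] = 0.0
            continue
        edges = {(a, b) for a, b in combinations(nbrs, 2) if g.has_edge(a, b)}
        out[v] = float(max(len(_reachable(nbrs, edges, u)) for u in nbrs))
    return out


def dmnc(g: nx.Graph, epsilon: float = 1.7) -> dict:
    _check(g)
    out = {}
    for v in g:
        nbrs = list(g[v])
        if not nbrs:
            out[v] = 0.0
            continue
        edges = {(a, b) for a, b in combinations(nbrs, 2) if g.has_edge(a, b)}
        best = max((_reachable(nbrs, edges, u) for u in nbrs), key=len)
        e = sum(1 for a, b in edges if a in best and b in best)
        out[v] = e / len(best) ** epsilon if e else 0.0
    return out


def mcc(g: nx.Graph) -> dict:
    """Enumerate every node subset; keep cliques maximal under inclusion;
    score v by the factorial sum with the edgeless-neighborhood fallback."""
    _check(g)
    nodes = list(g.nodes())
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques
               if not any(c < other for other in cliques)]
    out = {}
    for v in g:
        nbrs = list(g[v])
        if not any(g.has_edge(a, b) for a, b in combinations(nbrs, 2)):
            out[v] = float(len(nbrs))
            continue
        out[v] = float(sum(math.factorial(len(c) - 1)
                           for c in maximal if v in c))
    return out


def epc_exact(g: nx.Graph, retain_p: float = 0.5) -> dict:
    """Exact edge-percolation expectation by summing over all 2^m edge
    subsets, each weighted p^k (1-p)^(m-k)."""
    _check(g)
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    m = len(edges)
    if m > _EPC_MAX_EDGES:
        raise ValueError(f"epc_exact refuses graphs with more than "
                         f"{_EPC_MAX_EDGES} edges")
    nodes = list(g.nodes())
    n = len(nodes)
    out = {v: 0.0 for v in g}
    for mask in range(2 ** m):
        kept = {edges[i] for i in range(m) if mask >> i & 1}
        k = len(kept)
        w = retain_p ** k * (1.0 - retain_p) ** (m - k)
        if w == 0.0:
            continue
        for v in nodes:
            out[v] += w * len(_reachable(nodes, kept, v)) / n
    return out


_FUNCS = {
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


def brute_force_oracle(g: nx.Graph, index_name: str,
                       retain_p: Optional[float] = None) -> dict:
    """Dispatch to the brute-force computation of *index_name*; ``epc``
    returns the exact percolation expectation (needs ``retain_p``)."""
    _check(g)
    if index_name == "epc":
        return epc_exact(g, retain_p=0.5 if retain_p is None else retain_p)
    if index_name not in _FUNCS:
        raise ValueError(f"no oracle for index {index_name!r}")
    return _FUNCS[index_name](g)
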