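"""Synthetic study generator: planted-partition networks, seed lists and
mutation tables with the statistical structure the pipeline assumes.

The default ("paperlike") network is a 700-node planted-partition graph
with seven equal communities.  Edge probabilities were calibrated from the
closed-form identity for k equal communities with evenly spread
between-community degree,

    Q_planted = W/m - 1/k,

(W = within-community edges, m = total edges): p_in = 0.39, p_out = 0.052
puts the expected planted-partition modularity at ~0.41 at a mean degree of
~70, so a modular signaling-network-sized graph is contrasted against a
matched Erdős–Rényi null whose Louvain modularity sits near 0.09.

The mutation model draws protein lengths uniformly from 100-3000 residues
and mutation counts from ``Poisson(length * (mu + beta * centrality_pct))``
where ``centrality_pct`` in [0, 1] is the node's centrality percentile
(1 = most central).  ``beta = 0`` gives the null for type-I-error
calibration; ``coupling_for_rho`` converts a target Pearson correlation
into a coupling strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graphio import InteractionRecord, InteractionTable


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study (graph + seeds + mutations)."""

    sizes: tuple[int, ...] = (100,) * 7   # planted community sizes
    p_in: float = 0.39                    # within-community edge probability
    p_out: float = 0.052                  # between-community edge probability
    seed: int = 0
    mu: float = 0.002                     # base mutation rate per residue
    beta: float = 0.0                     # centrality-mutation coupling
    length_range: tuple[int, int] = (100, 3000)   # residues
    n_seed_core: int = 25                 # study seeds from community 0
    n_seed_scatter: int = 5               # study seeds from elsewhere

    def __post_init__(self):
        if not self.sizes or any(s < 1 for s in self.sizes):
            raise ValueError("community sizes must be positive")
        if not (self.p_in > self.p_out >= 0.0) or self.p_in > 1.0:
            raise ValueError("need p_in > p_out >= 0 and p_in <= 1")
        if self.mu < 0 or self.beta < 0:
            raise ValueError("mu and beta must be non-negative")

    @property
    def n(self) -> int:
        return sum(self.sizes)


def paperlike_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default modular study: 7 x 100 nodes, planted Q ~ 0.41."""
    return replace(SyntheticSpec(seed=seed), **overrides)


def null_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Structureless twin: p_in barely above p_out at the same density."""
    base = SyntheticSpec(seed=seed, p_in=0.1, p_out=0.0999)
    return replace(base, **overrides)


def _node_labels(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def planted_partition(spec: SyntheticSpec
                      ) -> tuple[nx.Graph, dict[str, int]]:
    """Sample a planted-partition graph; returns (graph, true assignment).

    Within-community node pairs are joined with probability ``p_in``,
    between-community pairs with ``p_out``.  The graph is simple by
    construction; labels are gene-symbol-like strings G0000, G0001, ...
    """
    n = spec.n
    labels = _node_labels(n)
    block = np.repeat(np.arange(len(spec.sizes)),
                      np.array(spec.sizes, dtype=int))
    rng = np.random.default_rng(spec.seed)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(block[iu] == block[ju], spec.p_in, spec.p_out)
    keep = rng.random(len(p)) < p
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from((labels[a], labels[b])
                     for a, b in zip(iu[keep], ju[keep]))
    truth = {labels[i]: int(block[i]) for i in range(n)}
    return g, truth


def centrality_percentile(ranks: dict | pd.Series) -> pd.Series:
    """Map fractional ranks (1 = most central) onto [0, 1] percentiles
    (1 = most central); constant 0.5 for a single node."""
    s = pd.Series(ranks, dtype=float)
    n = len(s)
    if n == 1:
        return pd.Series(0.5, index=s.index)
    return (n - s) / (n - 1)


def coupling_for_rho(rho: float, mu: float = 0.002,
                     length_range: tuple[int, int] = (100, 3000)) -> float:
    """Coupling strength beta giving an expected Pearson correlation of
    about *rho* between normalized frequency and centrality percentile.

    Delta-method approximation on the Poisson model: the percentile signal
    has variance beta^2/12; the Poisson noise of count/length has variance
    (mu + beta/2) * E[1/L] with L uniform on the length range.  Solving
    rho^2 = var_signal / (var_signal + var_noise) for beta gives a
    quadratic with one positive root.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must be in (0, 1)")
    lo, hi = length_range
    e_inv_len = math.log(hi / lo) / (hi - lo)
    a = (1.0 - rho ** 2) / 12.0
    b = rho ** 2 * e_inv_len / 2.0
    c = rho ** 2 * mu * e_inv_len
    return (b + math.sqrt(b * b + 4.0 * a * c)) / (2.0 * a)


def synth_mutations(g: nx.Graph, centrality_ranks: dict | pd.Series,
                    spec: SyntheticSpec,
                    rng: Optional[np.random.Generator] = None
                    ) -> pd.DataFrame:
    """Sample a gene/count/length mutation table for the graph's nodes.

    Counts follow Poisson(length * (mu + beta * percentile)); with
    ``beta = 0`` the table is independent of centrality (the null for
    calibration experiments).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    pct = centrality_percentile(centrality_ranks)
    genes = sorted(g.nodes())
    pct = pct.reindex(genes)
    if pct.isna().any():
        raise ValueError("centrality_ranks must cover every graph node")
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=len(genes))
    lam = lengths * (spec.mu + spec.beta * pct.to_numpy())
    counts = rng.poisson(lam)
    return pd.DataFrame({"gene": genes,
                         "count": counts.astype(int),
                         "length": lengths.astype(int)})


def synth_seed_study(spec: SyntheticSpec
                     ) -> tuple[list[str], InteractionTable,
                                nx.Graph, dict[str, int]]:
    """Generate a full synthetic study for end-to-end pipeline tests.

    Returns (seed list, interaction table of the full edge set, graph,
    true community assignment).  Seeds are drawn mostly from planted
    community 0 with a few scattered across the rest, mimicking a curated
    pathway-centric seed list embedded in a larger interactome.
    """
    g, truth = planted_partition(spec)
    rng = np.random.default_rng(spec.seed + 2)
    comm0 = sorted(v for v, c in truth.items() if c == 0)
    others = sorted(v for v, c in truth.items() if c != 0)
    n_core = min(spec.n_seed_core, len(comm0))
    n_scatter = min(spec.n_seed_scatter, len(others))
    seeds = sorted(rng.choice(comm0, size=n_core, replace=False).tolist()
                   + rng.choice(others, size=n_scatter,
                                replace=False).tolist())
    # stable synthetic STRING scores, all above the common 150 cutoff
    records = []
    for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
        score = int(rng.integers(150, 1000))
        records.append(InteractionRecord(u, v, score))
    return seeds, InteractionTable(records=records), g, truth


# ---------------------------------------------------------------------------
# Serialization of the three supported dialects

def write_seed_list(seeds: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(seeds) + "\n")


def write_edgelist(table: InteractionTable, path: str | Path) -> None:
    lines = ["# synthetic interactome, edge-list dialect"]
    lines += [f"{r.a}\t{r.b}" for r in table.records]
    Path(path).write_text("\n".join(lines) + "\n")


def write_biogrid_tab3(table: InteractionTable, path: str | Path) -> None:
    """Minimal BioGRID TAB3 file: header plus the columns the parser
    consumes (other TAB3 columns are filled with '-')."""
    header = ("#BioGRID Interaction ID\tOfficial Symbol Interactor A\t"
              "Official Symbol Interactor B\tExperimental System\t"
              "Throughput")
    lines = [header]
    for i, r in enumerate(table.records):
        lines.append(f"{i + 1}\t{r.a}\t{r.b}\t-\t-")
    Path(path).write_text("\n".join(lines) + "\n")


def write_string_links(table: InteractionTable, path: str | Path) -> None:
    lines = ["protein1 protein2 combined_score"]
    for r in table.records:
        score = 999 if r.score is None else r.score
        lines.append(f"{r.a} {r.b} {score}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mutation_table(mutations: pd.DataFrame, path: str | Path) -> None:
    mutations.loc[:, ["gene", "count", "length"]].to_csv(path, index=False)


def write_truth_labels(truth: dict[str, int], path: str | Path) -> None:
    lines = ["gene,community"]
    lines += [f"{v},{c}" for v, c in sorted(truth.items())]
    Path(path).write_text("\n".join(lines) + "\n")
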