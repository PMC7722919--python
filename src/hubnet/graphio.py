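"""Interaction-table parsing and seed-expanded network construction.

Three input dialects are supported, all plain text:

* ``edgelist`` — two tab-separated gene-symbol columns, ``#`` comments allowed;
* ``biogrid_tab3`` — BioGRID TAB3 export; only the two "Official Symbol
  Interactor A/B" columns are consumed;
* ``string_links`` — STRING links file (``protein1 protein2 combined_score``,
  whitespace-separated, header line), filtered by a combined-score threshold.

Networks are undirected simple graphs over uppercase gene symbols.  The
seed-expanded build mirrors the common PPI workflow: start from a curated
seed list, add the seeds' direct interaction partners, and keep every
database edge among the resulting node set (including partner-partner
edges).  Downstream topological analysis runs on the largest connected
component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import networkx as nx

log = logging.getLogger(__name__)

Dialect = Literal["edgelist", "biogrid_tab3", "string_links"]
DIALECTS = ("edgelist", "biogrid_tab3", "string_links")

_BIOGRID_COL_A = "official symbol interactor a"
_BIOGRID_COL_B = "official symbol interactor b"


class DialectError(ValueError):
    """Unknown or misconfigured input dialect."""


class EmptyInputError(ValueError):
    """A parse produced zero usable interaction records."""


@dataclass(frozen=True)
class InteractionRecord:
    a: str
    b: str
    score: Optional[int] = None  # STRING combined score, 0-1000

    def key(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass
class InteractionTable:
    """Deduplicated list of undirected interaction records."""

    records: list[InteractionRecord] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def partners(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for r in self.records:
            adj.setdefault(r.a, set()).add(r.b)
            adj.setdefault(r.b, set()).add(r.a)
        return adj


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def _dedup(pairs: Iterable[tuple[str, str, Optional[int]]],
           n_skipped: int) -> InteractionTable:
    seen: set[tuple[str, str]] = set()
    records: list[InteractionRecord] = []
    for a, b, score in pairs:
        if a == b:  # self-interactions never enter the graph
            continue
        rec = InteractionRecord(a, b, score)
        k = rec.key()
        if k in seen:
            continue
        seen.add(k)
        records.append(rec)
    return InteractionTable(records=records, n_skipped=n_skipped)


def parse_interactions(path: str | Path, dialect: Dialect,
                       score_min: int = 700) -> InteractionTable:
    """Parse an interaction file into a deduplicated :class:`InteractionTable`.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        One of ``edgelist``, ``biogrid_tab3``, ``string_links``; never sniffed.
    score_min:
        Minimum STRING combined score (0-1000); used only for
        ``string_links``.

    Raises
    ------
    DialectError
        If *dialect* is not one of the three supported names.
    EmptyInputError
        If no usable record survives parsing and filtering.
    """
    if dialect not in DIALECTS:
        raise DialectError(
            f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    lines = path.read_text().splitlines()

    pairs: list[tuple[str, str, Optional[int]]] = []
    skipped = 0

    if dialect == "edgelist":
        for line in lines:
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f for f in line.split("\t")]
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                skipped += 1
                continue
            pairs.append((_norm(fields[0]), _norm(fields[1]), None))

    elif dialect == "biogrid_tab3":
        header = None
        for line in lines:
            if not line.strip():
                continue
            cols = [c.strip().lstrip("#").strip().lower()
                    for c in line.split("\t")]
            if header is None:
                header = cols
                try:
                    ia = header.index(_BIOGRID_COL_A)
                    ib = header.index(_BIOGRID_COL_B)
                except ValueError as err:
                    raise DialectError(
                        "biogrid_tab3 header lacks the official-symbol "
                        "interactor columns") from err
                continue
            fields = line.split("\t")
            if len(fields) <= max(ia, ib):
                skipped += 1
                continue
            a, b = _norm(fields[ia]), _norm(fields[ib])
            if not a or not b or a == "-" or b == "-":
                skipped += 1
                continue
            pairs.append((a, b, None))

    else:  # string_links
        saw_header = False
        for line in lines:
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if not saw_header:
                saw_header = True
                if fields and not fields[-1].lstrip("-").isdigit():
                    continue  # header row
            if len(fields) < 3:
                skipped += 1
                continue
            try:
                score = int(fields[2])
            except ValueError:
                skipped += 1
                continue
            if score < score_min:
                continue
            pairs.append((_norm(fields[0]), _norm(fields[1]), score))

    if skipped:
        log.warning("parse_interactions(%s, %s): skipped %d malformed rows",
                    path.name, dialect, skipped)
    table = _dedup(pairs, skipped)
    if not table.records:
        raise EmptyInputError(
            f"no usable interaction records in {path} (dialect={dialect})")
    return table


def read_seeds(path: str | Path) -> list[str]:
    """Read a seed list, one gene symbol per line; ``#`` comments allowed.

    Symbols are uppercased and deduplicated preserving first occurrence.
    """
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        s = _norm(line)
        if s not in seen:
            seen.add(s)
            out.append(s)
    if not out:
        raise EmptyInputError(f"seed list {path} is empty")
    return out


def build_network(seeds: list[str], table: InteractionTable,
                  expand: Literal["none", "one_hop"] = "one_hop") -> nx.Graph:
    """Build the seed network, optionally expanded by direct partners.

    With ``expand="one_hop"`` the node set is the seeds plus every direct
    interaction partner of a seed; the edge set is every table edge with
    both endpoints in that node set, so partner-partner edges are kept.
    Partners-of-partners are never added.  With ``expand="none"`` the graph
    is the induced subgraph on the seeds.  Seeds absent from the table are
    retained as isolated nodes.
    """
    if not seeds:
        raise ValueError("seed list must be non-empty")
    if expand not in ("none", "one_hop"):
        raise ValueError(f"unknown expansion mode {expand!r}")
    seed_set = {_norm(s) for s in seeds}
    adj = table.partners()
    nodes = set(seed_set)
    if expand == "one_hop":
        for s in seed_set:
            nodes |= adj.get(s, set())
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for r in table.records:
        if r.a in nodes and r.b in nodes and r.a != r.b:
            g.add_edge(r.a, r.b)
    return g


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component; ties go to the component
    containing the lexicographically smallest node label."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comps = list(nx.connected_components(g))
    max_size = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == max_size), key=min)
    return g.subgraph(best).copy()


def write_graph_tsv(g: nx.Graph, path: str | Path) -> None:
    """Serialize a graph as edge-list TSV; isolated nodes get single-field
    lines so the round trip preserves the node set exactly."""
    lines = ["# hubnet graph: <a>\\t<b> per edge; single field = isolated node"]
    for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
        lines.append(f"{u}\t{v}")
    for n in sorted(nx.isolates(g)):
        lines.append(str(n))
    Path(path).write_text("\n".join(lines) + "\n")


def read_graph_tsv(path: str | Path) -> nx.Graph:
    """Inverse of :func:`write_graph_tsv`."""
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f for f in line.split("\t") if f.strip()]
        if len(fields) == 1:
            g.add_node(_norm(fields[0]))
        else:
            a, b = _norm(fields[0]), _norm(fields[1])
            if a != b:
                g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise EmptyInputError(f"graph file {path} is empty")
    return g
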