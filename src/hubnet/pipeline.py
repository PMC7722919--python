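"""End-to-end pipeline: network build, centrality ranking, modularity with
a random-graph null, and mutation-burden correlation, from one config.

Outputs (all plain text, reproducible bit-for-bit from config + seed):

* ``graph.tsv``, ``graph_summary.json`` — analysis graph and its n/m stats;
* ``scores.csv`` — node x index centrality scores;
* ``informativeness.csv`` — distinct-score fractions and flags;
* ``ranks.csv`` — fractional ranks plus group/total/weighted averages;
* ``top20.csv`` / ``top20.txt`` — top-k nodes per informative index;
* ``communities.csv``, ``community_sizes.csv`` — Louvain partition and its
  size distribution;
* ``null_comparison.csv`` — observed Q vs G(n,m) null replicates;
* ``correlations.csv`` — mutation-burden correlation per rank list
  (skipped and flagged when no mutation table is configured);
* ``manifest.json`` — every parameter and seed of the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd
import yaml

from . import centrality as ct
from . import community as cm
from . import graphio, mutations as mu, ranking as rk

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seeds_path: str
    interactions_path: str
    dialect: str = "edgelist"
    score_min: int = 700
    expand: str = "one_hop"
    lcc: bool = True
    mutations_path: Optional[str] = None
    indices: tuple[str, ...] = ct.INDEX_NAMES
    epc_trials: int = 1000
    epc_p: float = 0.5
    weights: tuple[float, float, float] = rk.DEFAULT_WEIGHTS
    min_distinct_fraction: float = rk.DEFAULT_MIN_DISTINCT_FRACTION
    resolution: float = 1.0
    null_replicates: int = 3
    correlation_method: str = "pearson"
    top_k: int = 20
    seed: int = 0
    outdir: str = "hubnet_out"

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.null_replicates < 1:
            raise ValueError("null_replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("indices", "weights"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def render_top20(table: rk.RankTable, k: int = 20,
                 columns: tuple[str, ...] = ct.INFORMATIVE_ORDER
                 ) -> pd.DataFrame:
    """Top-k grid, one column per informative index (top-n when n < k)."""
    k = min(k, len(table.nodes))
    data = {col: rk.top_k(table, col, k) for col in columns}
    return pd.DataFrame(data, index=pd.RangeIndex(1, k + 1, name="No"))


def _fmt_text_table(frame: pd.DataFrame) -> str:
    cols = ["No"] + list(frame.columns)
    rows = [[str(i)] + [str(frame.at[i, c]) for c in frame.columns]
            for i in frame.index]
    widths = [max(len(c), *(len(r[j]) for r in rows))
              for j, c in enumerate(cols)]
    lines = ["  ".join(c.ljust(w) for c, w in zip(cols, widths))]
    lines += ["  ".join(x.ljust(w) for x, w in zip(row, widths))
              for row in rows]
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict.  Any stage error removes
    the partial outputs and raises :class:`StageError`."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def _write(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    stage = "setup"
    t_all = time.time()
    try:
        # ---- build -----------------------------------------------------
        stage = "build_network"
        t0 = time.time()
        seeds = graphio.read_seeds(config.seeds_path)
        table = graphio.parse_interactions(
            config.interactions_path, config.dialect,
            score_min=config.score_min)
        g_full = graphio.build_network(seeds, table, expand=config.expand)
        g = graphio.largest_connected_component(g_full) if config.lcc \
            else g_full
        _write("graph.tsv", lambda p: graphio.write_graph_tsv(g, p))
        summary = {
            "n_seeds": len(seeds),
            "n_nodes_full": g_full.number_of_nodes(),
            "n_edges_full": g_full.number_of_edges(),
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "lcc": config.lcc,
        }
        _write("graph_summary.json", lambda p: p.write_text(
            json.dumps(summary, indent=2) + "\n"))
        manifest["stages"][stage] = {**summary,
                                     "seconds": round(time.time() - t0, 3)}

        # ---- centrality ------------------------------------------------
        stage = "centrality"
        t0 = time.time()
        scores = ct.compute_indices(g, config.indices,
                                    epc_trials=config.epc_trials,
                                    epc_p=config.epc_p, seed=config.seed)
        _write("scores.csv", lambda p: scores.to_csv(p))
        manifest["stages"][stage] = {"indices": list(config.indices),
                                     "epc_seed": config.seed,
                                     "seconds": round(time.time() - t0, 3)}

        # ---- ranking ---------------------------------------------------
        stage = "ranking"
        t0 = time.time()
        report = rk.informativeness(
            scores, min_distinct_fraction=config.min_distinct_fraction)
        _write("informativeness.csv",
               lambda p: report.to_frame().to_csv(p))
        ranks = scores.apply(rk.scores_to_ranks)
        rank_table = rk.combine_ranks(ranks, weights=config.weights)
        _write("ranks.csv", lambda p: rank_table.to_frame().to_csv(p))
        top = render_top20(rank_table, k=config.top_k)
        _write("top20.csv", lambda p: top.to_csv(p))
        _write("top20.txt", lambda p: p.write_text(_fmt_text_table(top)))
        manifest["stages"][stage] = {
            "non_informative": sorted(k for k, v in
                                      report.informative.items() if not v),
            "weights": list(config.weights),
            "seconds": round(time.time() - t0, 3)}

        # ---- modularity ------------------------------------------------
        stage = "modularity"
        t0 = time.time()
        result = cm.louvain(g, resolution=config.resolution,
                            seed=config.seed)
        assign = pd.DataFrame(
            sorted(result.assignment.items()),
            columns=["gene", "community"])
        _write("communities.csv", lambda p: assign.to_csv(p, index=False))
        _write("community_sizes.csv",
               lambda p: cm.size_distribution(result).to_csv(p, index=False))
        nulls = cm.random_null(g.number_of_nodes(), g.number_of_edges(),
                               replicates=config.null_replicates,
                               resolution=config.resolution,
                               seed=config.seed)
        comp = pd.DataFrame({
            "graph": ["observed"] + [f"null_{i}" for i in
                                     range(len(nulls))],
            "modularity_q": [result.modularity_q] +
                            [r.modularity_q for r in nulls],
            "n_communities": [result.n_communities] +
                             [r.n_communities for r in nulls],
        })
        _write("null_comparison.csv", lambda p: comp.to_csv(p, index=False))
        manifest["stages"][stage] = {
            "modularity_q": result.modularity_q,
            "n_communities": result.n_communities,
            "null_q": [r.modularity_q for r in nulls],
            "seconds": round(time.time() - t0, 3)}

        # ---- mutation correlation --------------------------------------
        stage = "mutation_correlation"
        t0 = time.time()
        if config.mutations_path is None:
            manifest["stages"][stage] = {"skipped": True,
                                         "reason": "no mutation table"}
            log.warning("no mutation table configured; "
                        "correlation stage skipped")
        else:
            sep = "\t" if str(config.mutations_path).endswith(
                (".tsv", ".txt")) else ","
            raw = pd.read_csv(config.mutations_path, sep=sep)
            norm = mu.normalize_mutations(raw)
            corr = mu.correlation_table(norm, rank_table.to_frame(),
                                        method=config.correlation_method)
            _write("correlations.csv",
                   lambda p: corr.to_csv(p, index=False))
            manifest["stages"][stage] = {
                "method": config.correlation_method,
                "n_genes": int(norm.shape[0]),
                "seconds": round(time.time() - t0, 3)}

        stage = "manifest"
        manifest["total_seconds"] = round(time.time() - t_all, 3)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest

    except Exception as err:  # remove partial outputs, name the stage
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise StageError(stage, err) from err
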