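"""Rank aggregation for centrality-based hub prioritization.

Scores become fractional ranks (rank 1 = most central, ties averaged).
Indices whose score lists are mostly repetitive are flagged non-informative
and excluded from aggregation.  The remaining eight indices are combined in
three groups:

* group 1 — interaction among neighbors: DMNC, clustering coefficient;
* group 2 — distance / information flow: closeness, radiality, betweenness,
  stress, EPC;
* degree stands alone.

The unweighted combination averages all eight rank lists; the weighted
combination is ``0.1 * group1 + 0.7 * group2 + 0.2 * degree-rank``,
reflecting the working hypothesis that information-flow indices are the
better essentiality predictors in signaling networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GROUP1 = ("dmnc", "clustering_coefficient")
GROUP2 = ("closeness", "radiality", "betweenness", "stress", "epc")
REQUIRED_INDICES = ("degree",) + GROUP1 + GROUP2

DEFAULT_WEIGHTS = (0.1, 0.7, 0.2)  # (group1, group2, degree)
DEFAULT_MIN_DISTINCT_FRACTION = 0.10


def scores_to_ranks(scores: dict | pd.Series) -> pd.Series:
    """Descending fractional ranks: the best score gets rank 1; tied scores
    get the mean of the positions they span."""
    s = pd.Series(scores, dtype=float)
    if s.empty:
        raise ValueError("cannot rank an empty score vector")
    return s.rank(ascending=False, method="average")


@dataclass
class InformativenessReport:
    """Per-index distinct-score fractions and informativeness flags."""

    distinct_fraction: dict[str, float] = field(default_factory=dict)
    informative: dict[str, bool] = field(default_factory=dict)
    threshold: float = DEFAULT_MIN_DISTINCT_FRACTION

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distinct_fraction": pd.Series(self.distinct_fraction),
            "informative": pd.Series(self.informative),
        }).rename_axis("index_name")


def informativeness(scores_by_index: pd.DataFrame,
                    min_distinct_fraction: float = DEFAULT_MIN_DISTINCT_FRACTION
                    ) -> InformativenessReport:
    """Flag indices whose score list is mostly repetitive.

    An index is non-informative when its number of distinct scores divided
    by the node count falls below *min_distinct_fraction*.
    """
    rep = InformativenessReport(threshold=min_distinct_fraction)
    n = len(scores_by_index)
    for name in scores_by_index.columns:
        frac = scores_by_index[name].nunique() / n if n else 0.0
        rep.distinct_fraction[name] = frac
        rep.informative[name] = frac >= min_distinct_fraction
    return rep


@dataclass
class RankTable:
    """Per-node fractional ranks plus group and combined averages."""

    ranks: pd.DataFrame                 # node x index fractional ranks
    combined: pd.DataFrame              # group1/2/3, total, weighted columns
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    @property
    def nodes(self) -> list:
        return list(self.ranks.index)

    def to_frame(self) -> pd.DataFrame:
        return self.ranks.join(self.combined)


def combine_ranks(ranks: pd.DataFrame,
                  weights: tuple[float, float, float] = DEFAULT_WEIGHTS
                  ) -> RankTable:
    """Build the group, total and weighted rank averages.

    *ranks* must contain a fractional-rank column for each of the eight
    informative indices (degree, DMNC, clustering coefficient, closeness,
    radiality, betweenness, stress, EPC).  Extra columns are carried along
    untouched.
    """
    missing = [c for c in REQUIRED_INDICES if c not in ranks.columns]
    if missing:
        raise ValueError(f"missing required rank columns: {missing}")
    w1, w2, wd = weights
    if abs(w1 + w2 + wd - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    g1 = ranks.loc[:, list(GROUP1)].mean(axis=1)
    g2 = ranks.loc[:, list(GROUP2)].mean(axis=1)
    deg = ranks["degree"]
    combined = pd.DataFrame({
        "group1_avg": g1,
        "group2_avg": g2,
        "group3_avg": (g1 + g2 + deg) / 3.0,
        "total_avg": ranks.loc[:, list(REQUIRED_INDICES)].mean(axis=1),
        "weighted_avg": w1 * g1 + w2 * g2 + wd * deg,
    }, index=ranks.index)
    return RankTable(ranks=ranks.copy(), combined=combined,
                     weights=(w1, w2, wd))


def top_k(table: RankTable | pd.DataFrame, column: str, k: int = 20) -> list:
    """The *k* best nodes of a rank column (lowest value first); ties broken
    by node label."""
    frame = table.to_frame() if isinstance(table, RankTable) else table
    if column not in frame.columns:
        raise ValueError(f"no such rank column: {column!r}")
    if k > len(frame):
        raise ValueError(f"k={k} exceeds table size {len(frame)}")
    order = sorted(frame.index, key=lambda v: (frame.at[v, column], str(v)))
    return order[:k]
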