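"""Length-normalized mutation burden and its correlation with centrality.

Mutation counts per gene are divided by protein length (residues) to give a
per-residue mutation frequency, then correlated against centrality rank
lists.  Since rank 1 denotes the most central node, a "more central genes
are more mutated" association shows up as a negative coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class MutationRecord:
    gene: str
    count: int
    length: int

    @property
    def normalized(self) -> float:
        return self.count / self.length


@dataclass(frozen=True)
class CorrelationResult:
    index_name: str
    coefficient: float
    p_value: float
    n_genes: int


def normalize_mutations(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene/count/length table and add the per-residue frequency.

    Returns a copy with uppercase gene symbols and a ``normalized`` column
    (count / length), sorted by decreasing normalized frequency.

    Raises ``ValueError`` naming the offending gene for non-positive
    lengths, negative counts, or duplicate gene symbols.
    """
    required = {"gene", "count", "length"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"mutation table lacks columns: {sorted(missing)}")
    df = table.loc[:, ["gene", "count", "length"]].copy()
    df["gene"] = df["gene"].astype(str).str.strip().str.upper()
    dup = df["gene"][df["gene"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene symbol: {dup.iloc[0]}")
    bad_len = df.loc[df["length"] <= 0, "gene"]
    if not bad_len.empty:
        raise ValueError(f"non-positive protein length for gene "
                         f"{bad_len.iloc[0]}")
    bad_cnt = df.loc[df["count"] < 0, "gene"]
    if not bad_cnt.empty:
        raise ValueError(f"negative mutation count for gene {bad_cnt.iloc[0]}")
    df["normalized"] = df["count"] / df["length"]
    return (df.sort_values(["normalized", "gene"],
                           ascending=[False, True])
            .reset_index(drop=True))


def correlate(mutations: pd.DataFrame, ranks: dict | pd.Series,
              method: Literal["pearson", "spearman"] = "pearson",
              index_name: str = "") -> CorrelationResult:
    """Correlate normalized mutation frequency against a rank list.

    Genes are inner-joined on symbol; at least three overlapping genes are
    required.  Returns the two-sided coefficient and p-value.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    rank_s = pd.Series(ranks, dtype=float)
    mut = mutations.set_index("gene")["normalized"] \
        if "normalized" in mutations.columns \
        else normalize_mutations(mutations).set_index("gene")["normalized"]
    common = mut.index.intersection(rank_s.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} genes overlap between the "
                         "mutation table and the rank list; need >= 3")
    x = mut.loc[common].to_numpy()
    y = rank_s.loc[common].to_numpy()
    if x.min() == x.max() or y.min() == y.max():
        raise ValueError("correlation undefined: zero variance on one side")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(index_name=index_name, coefficient=float(r),
                             p_value=float(p), n_genes=len(common))


def correlation_table(mutations: pd.DataFrame, ranks: pd.DataFrame,
                      method: Literal["pearson", "spearman"] = "pearson",
                      columns: Optional[list[str]] = None) -> pd.DataFrame:
    """One correlation row per rank column (indices and combined averages).

    *ranks* is a node-indexed frame of fractional ranks, e.g.
    ``RankTable.to_frame()``.  Rows where the correlation is undefined
    (zero variance) are reported with NaN coefficient and p-value.
    """
    cols = columns if columns is not None else list(ranks.columns)
    rows = []
    for col in cols:
        try:
            res = correlate(mutations, ranks[col], method=method,
                            index_name=col)
            rows.append((col, res.coefficient, res.p_value, res.n_genes))
        except ValueError as err:
            if "zero variance" not in str(err):
                raise
            n = len(pd.Index(mutations["gene"].str.upper())
                    .intersection(ranks.index))
            rows.append((col, float("nan"), float("nan"), n))
    return pd.DataFrame(rows, columns=["index_name", "correlation",
                                       "p_value", "n_genes"])
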