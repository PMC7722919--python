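# Methods

## Scope and model

`hubnet` analyzes an undirected simple graph of proteins (uppercase gene
symbols) built from a curated seed list and an interaction table. One-hop
expansion adds the seeds' direct interaction partners and keeps every
table edge among the resulting node set, including partner–partner edges;
partners-of-partners are never added as nodes. Seeds absent from the table
stay as isolated nodes and are shed naturally when the largest connected
component (LCC) is taken. LCC ties are broken toward the component
containing the lexicographically smallest label, for determinism.

Identifiers are normalized by uppercasing and whitespace-trimming only; no
alias or ortholog mapping is attempted, so input tables must already use a
consistent symbol namespace.

## Centrality definitions and numerical choices

All twelve indices are "higher = more central". On disconnected graphs the
distance-based indices are computed per component and unreachable pairs
contribute nothing; closeness uses the harmonic form (sum of reciprocal
distances) precisely so disconnection needs no special casing.

Decisions that are genuinely conventions, fixed here and enforced by the
brute-force oracles:

* **Betweenness** is unnormalized and counts each unordered pair once.
* **Stress** counts raw geodesics through a node; computed by a
  Brandes-style accumulation (`σ_sv · τ_s(v)` per source, halved for the
  undirected double count), which the oracle verifies against exhaustive
  path enumeration.
* **Radiality** of v is `Σ_w (Δ+1−d(v,w)) / (n_c−1)` with Δ and `n_c` the
  diameter and size of v's component; isolated nodes score 0.
* **EcCentricity** is the reciprocal of graph eccentricity (so higher is
  more central, like everything else); singleton components score 0.
* **Bottleneck**: for each root s, a deterministic BFS shortest-path tree
  is built with each node's parent being its *smallest-label* neighbor one
  step closer to s; v scores one point per root whose tree gives v a
  subtree (v included) of *strictly* more than a quarter of the tree's
  nodes. Parent tie-break and strict inequality are unstated in the
  literature; both are fixed for reproducibility. Consequence: bottleneck
  commutes with order-preserving relabelings but not with arbitrary label
  permutations (the tests check exactly that).
* **EPC** keeps each edge with probability p (default 0.5) in each of K
  trials (default 1000) and averages the reachable fraction |C(v)|/n.
  The per-n normalization differs from some published constants by a fixed
  positive factor; rank order, the only thing aggregation consumes, is
  unaffected. Scores are reproducible bit-for-bit under a fixed seed, and
  Monte Carlo variance shrinks as 1/K (tested at K ∈ {100, 10000}). On
  densely connected graphs EPC saturates at 1.0 for every node and is then
  flagged non-informative by the ranking stage — expected behavior, not an
  error.
* **MNC / DMNC** use the largest connected component of the open
  neighborhood; DMNC divides its edge count by |V|^1.7 and scores 0 when
  the neighborhood has no edge.
* **MCC** sums (|C|−1)! over maximal cliques containing v (Bron–Kerbosch
  with pivoting via networkx). When v's neighborhood is edgeless every
  maximal clique through v is a single edge, so the sum equals the degree
  — the degree fallback is automatic rather than a special case.

Brute-force oracles (`hubnet.oracle`) recompute every deterministic index
by exhaustive enumeration (all simple paths, all node subsets, all 2^m
edge subsets for the exact EPC expectation) and refuse graphs above 10
nodes. The equivalence tests run them against the fast implementations on
a fixed catalog (paths, star, cliques, cycle, barbell) plus 50 seeded
random graphs of up to 7 nodes.

## Informativeness and aggregation

The informativeness filter operationalizes "mostly repetitive score lists"
as: an index is non-informative when its number of distinct scores divided
by the node count falls below 10% (configurable). Which indices trip the
filter depends on topology — on sparse scale-free-like PPI networks it is
typically Bottleneck, MCC and EcCentricity; on dense synthetic graphs EPC
and even Degree can saturate instead.

Aggregation always uses ranks, never raw scores. Fractional (average)
ranking is used everywhere, so tied scores share the mean of the positions
they span and each index's ranks sum to n(n+1)/2 exactly. The combined
columns are

* group 1 = mean rank of {DMNC, clustering coefficient},
* group 2 = mean rank of {closeness, radiality, betweenness, stress, EPC},
* group 3 = mean of {group 1, group 2, degree rank},
* total = unweighted mean over all eight informative indices,
* weighted = 0.1·group1 + 0.7·group2 + 0.2·degree rank.

The weights (0.1, 0.7, 0.2) encode the hypothesis that information-flow
indices predict essentiality best in signaling networks; they are
configurable but must sum to 1. Top-k listings break ties
lexicographically.

## Modularity and the null model

Louvain optimization is delegated to networkx's implementation of
Blondel's method (resolution and seed supported); the reported Q is always
re-evaluated with `modularity_of`, a direct implementation of
`Q(γ) = Σ_c [e_c/m − γ(d_c/2m)²]` that serves as an optimizer-independent
oracle (it is itself cross-checked against networkx's modularity on random
partitions). An edgeless graph returns all-singleton communities with
Q = 0 by convention.

The null model is G(n, m): uniform over simple graphs with exactly the
observed node and edge counts, the minimal null consistent with "random
graphs of the same size". Three replicates by default, each with a seed
derived deterministically from the stage seed. No degree-preserving
(configuration-model) null is offered — matched size only, by design.

A converged Louvain on G(2039, 76924) (mean degree ≈ 75) finds Q ≈ 0.096
with ~9–10 communities; networkx, igraph's multilevel implementation, and
a plain reimplementation of the two-phase algorithm agree to ~0.005.
Older GUI implementations of the same algorithm can stop at slightly
worse optima (Q ≈ 0.085 has been reported for graphs of this size); the
separation argument — a modular network's Q ≈ 0.41 is ~4× any of these
null values — is insensitive to that difference.

## Mutation correlation

Mutation burden is normalized per residue (count/length); zero or negative
lengths and duplicate gene symbols are hard errors. Genes missing from
either side are dropped by an inner join on symbol rather than imputed as
zero — the conservative reading when a mutation table covers only part of
the network. Pearson is the default method (matching a plain `cor.test`),
Spearman is exposed. At least 3 overlapping genes are required; zero
variance on either side makes the correlation undefined (error from
`correlate`, NaN row from `correlation_table`).

## Synthetic data: what it emulates and what it does not

`planted_partition` samples a stochastic block model with equal-size
blocks: within-community edge probability `p_in`, between `p_out`. The
paperlike preset (7 × 100 nodes, p_in = 0.39, p_out = 0.052) was
calibrated analytically from the identity `Q_planted = W/m − 1/k` for k
equal communities (W = within-community edges): expected planted Q ≈ 0.41
at mean degree ≈ 70, dense enough that the matched G(n,m) null's Louvain
Q ≈ 0.09 and the modular-vs-null separation is ≥ 4×. At 700 nodes the
full modularity stage runs in ~2 s; the test and acceptance problem sizes
(150–700 nodes) were chosen so the complete suite stays fast while
preserving the 7-community shape.

The mutation model draws protein lengths uniformly from 100–3000 residues
and counts from `Poisson(length · (μ + β · pct(v)))`, where `pct(v) ∈
[0, 1]` is v's centrality percentile (1 = most central). μ defaults to
0.002 mutations per residue — a synthetic scale giving comfortable Poisson
counts, deliberately not a claim about real somatic burden. β = 0 is the
null used for type-I-error calibration; `coupling_for_rho` inverts a
delta-method approximation of the model's signal-to-noise ratio to find
the β giving a target Pearson ρ (simulation confirms ρ = 0.6 is hit within
±0.05). Because the Poisson noise variance depends on the sampled length,
the normalized frequencies are mildly heteroscedastic, and the Pearson
type-I error hovers slightly above the nominal 5% (≈ 0.03–0.08 across
seeds at 200 replicates).

Features of real PPI data the generator does *not* emulate: scale-free
degree distributions (blocks are internally Erdős–Rényi), unequal
community sizes, assortativity, and annotation noise in gene symbols.
Passing tests therefore demonstrate correctness of the pipeline's
computations and calibration of its statistics under a clean block model,
not robustness to real-interactome artifacts.

## Pipeline and reproducibility

All randomness funnels through per-stage seeds recorded in
`manifest.json`; reruns of the same config produce byte-identical outputs
(the manifest differs only in wall-clock timings). Any stage failure
removes partial outputs and raises an error naming the stage. When no
mutation table is configured the correlation stage is skipped and flagged
in the manifest rather than treated as an error. Community-size
distributions are emitted as CSV; plotting is left to the user (matplotlib
is an optional extra, not a pipeline dependency).

## Known limitations

* No edge weights, directed variants, or approximate betweenness; graphs
  beyond ~10⁴ nodes will be slow in the all-pairs stages.
* MCC relies on maximal-clique enumeration, which can blow up on
  pathologically dense graphs; PPI LCCs at the intended scale are sparse
  outside hub cliques.
* The informativeness filter is a heuristic threshold on distinct-score
  fraction; 10% is a reasonable operationalization of "mostly repetitive",
  not a statistical test.
* G(n,m) is the only null; conclusions about *which* nodes drive
  modularity need a degree-preserving null that is out of scope here.
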