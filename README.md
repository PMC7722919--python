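# hubnet

Hub-gene prioritization for seed-expanded protein–protein interaction (PPI)
networks, with a modularity null model and a mutation-burden correlation —
the standard workflow behind network-based target nomination in cancer
systems biology (e.g. ranking regulators of sodium–iodide symporter
expression in anaplastic thyroid carcinoma from a curated seed list of
signaling and transcription-factor proteins).

The pipeline:

1. **Network build** — parse an interaction table (plain edge list, BioGRID
   TAB3, or STRING links with a combined-score cutoff), expand a curated
   seed list by its direct interaction partners (keeping partner–partner
   edges), and extract the largest connected component (LCC).
2. **Centrality** — score every node with twelve cytoHubba-family indices:
   Degree, Betweenness, Closeness (harmonic), Bottleneck, Radiality,
   Stress, Clustering coefficient, EcCentricity (reciprocal), EPC
   (edge-percolated component, Monte Carlo), MNC, DMNC, and MCC (maximal
   clique centrality). Each deterministic index has an independent
   brute-force oracle used by the test suite.
3. **Rank aggregation** — convert scores to fractional ranks (rank 1 =
   most central), flag indices whose score lists are mostly repetitive as
   non-informative, and combine the eight informative rank lists into
   group averages and a weighted average

   `W(v) = 0.1·G1(v) + 0.7·G2(v) + 0.2·rank_degree(v)`

   with `G1` = mean rank of {DMNC, clustering coefficient} and `G2` = mean
   rank of the information-flow indices {closeness, radiality, betweenness,
   stress, EPC}.
4. **Modularity** — Louvain (Blondel's two-phase method) at resolution γ,
   scoring partitions with Newman's modularity
   `Q(γ) = Σ_c [e_c/m − γ(d_c/2m)²]`, and comparing the observed Q against
   Louvain on Erdős–Rényi G(n, m) random graphs with matched node and edge
   counts.
5. **Mutation correlation** — divide per-gene mutation counts by protein
   length (mutations per residue) and correlate the normalized burden with
   every rank list (Pearson default, Spearman available). Because rank 1
   is most central, "more central → more mutated" appears as a *negative*
   coefficient.

A synthetic-data module generates planted-partition networks, seed lists,
and Poisson mutation tables with optional centrality coupling, so the whole
pipeline is testable offline.

## Worked example

Simulate a modular study (350 proteins in 7 planted communities, with
mutation counts coupled to centrality) and run the full pipeline:

```bash
hubnet simulate --preset paperlike --n 350 --communities 7 \
    --beta 0.0064 --seed 11 -o demo
cat > demo/config.yaml <<EOF
seeds_path: demo/seeds.txt
interactions_path: demo/interactions.tsv
mutations_path: demo/mutations.csv
seed: 11
outdir: demo/out
EOF
hubnet run --config demo/config.yaml
```

The run takes ~10 s and reports, among other things:

```
"modularity": {
  "modularity_q": 0.4026420550210511,
  "n_communities": 7,
  "null_q": [0.1321638133138573, 0.14483668860275487, 0.14336923746374602]
}
```

i.e. the planted 7-community structure is found (Q ≈ 0.40) and sits far
above the matched random-graph null (Q ≈ 0.13–0.14). `demo/out/` then
contains the report bundle: `top20.csv` (top-20 proteins per informative
index), `ranks.csv` (all fractional ranks plus group/total/weighted
averages), `communities.csv` + `community_sizes.csv`,
`null_comparison.csv`, and `correlations.csv`. With the coupling used
above, the weighted-average rank row of `correlations.csv` reads

```
weighted_avg  correlation -0.560  p_value 2.1e-27  n_genes 315
```

— the injected "central genes are more mutated" signal detected as a
negative rank correlation. Each stage is also available as its own
subcommand (`hubnet build-network`, `centrality`, `rank`, `modularity`,
`mutcorr`), reading and writing plain TSV/CSV.

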