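# coexnet

Differential gene co-expression network analysis for matched
normal/tumor cohorts.

## The problem

In bulk RNA-seq cohorts with paired healthy and tumor samples, genes
that are co-expressed in healthy tissue frequently lose that
coordination in the tumor. Representing each condition as a weighted
co-expression graph makes this loss measurable: tumor networks shrink
(fewer connected genes and far fewer edges), central regulators lose
centrality, communities fragment, and shortest paths between regulatory
gene classes — oncogenes and epigenetic regulators in particular —
lengthen or break entirely. `coexnet` is a reusable, tested pipeline
for this analysis, aimed at computational biologists who want the whole
chain — edge construction, graph algorithms, perturbation statistics,
gene-set over-representation, and graph-database export — reproducible
from a single seed.

## The model

For each condition, every gene pair's Spearman correlation ρ is
computed across samples. Pairs with |ρ| > 0.99 are discarded (in
FPKM-like data these come from near-zero expression of both genes, not
biology). Surviving coefficients are soft-thresholded: the weight is
w = ρ⁶ and the pair becomes an edge iff w > 0.25, i.e. an edge exists
iff 0.25^(1/6) ≈ 0.794 < |ρ| ≤ 0.99. The two condition subnetworks are
then analyzed with

- **weighted PageRank** in the unnormalized convention
  s(n) = (1−d) + d·Σ_m s(m)·w(m,n)/S(m) with d = 0.85, so an isolated
  node scores exactly 0.15;
- **Louvain** weighted-modularity community detection (resolution 1,
  seeded, with deterministic multi-starts and a Kernighan–Lin escape
  pass);
- **Dijkstra** shortest paths between all oncogene × epigenetic-
  regulator pairs (hop counts by default, inverse-weight costs
  optionally);
- **hypergeometric over-representation** of gene sets in communities of
  ≥ 50 genes, BH-corrected.

Tumor-vs-normal perturbation is summarized as node/edge fold changes,
lost class-pair edges, per-gene centrality-shift categories, per-
community degree-change distributions, and path-length statistics. A
synthetic-data generator plants co-expression modules, regulatory gene
classes, tumor module dissolution, rewiring and gained hubs, so every
stage can be validated against known ground truth. See
`docs/methods.md` for the full model description.

## Worked example

```python
from coexnet import (
    SyntheticConfig, generate_dataset, DifferentialCoexpressionModel,
)

dataset = generate_dataset(SyntheticConfig(seed=8))   # 2,000 genes x 60 samples
model = DifferentialCoexpressionModel(
    dataset.normal, dataset.tumor, dataset.annotation,
    min_community_size=30,
)
results = model.fit(seed=8)
print(results.summary())
```

prints

```
Differential Co-expression Network Results
==========================================================
edge rule: weight = rho^6 > 0.25, |rho| <= 0.99
pagerank damping: 0.85   path mode: hops
----------------------------------------------------------
                                normal         tumor
nodes                              200           150
edges                             3900          2505
communities (normal)                 5      Q=0.7998
communities (tumor)                  4      Q=0.6893
----------------------------------------------------------
node fold (normal/tumor): 1.333   edge fold: 1.557
centrality shift fractions:
  decreased              60.4%
  relative_increase       8.3%
  absolute_increase      31.3%
  unchanged               0.0%
class-pair paths (ONCOGENE-EPIGENETIC): mean finite 1.00 -> 1.17, infinite 39597 -> 39615
```

Reading this: the generator planted five 40-gene modules (200 connected
genes) and dissolved two of them in the tumor, whose network keeps
3 × 40 module genes plus 30 gained hubs (150 nodes) — a 1.33-fold node
and 1.56-fold edge loss. Louvain recovers the planted modules as
communities. Most genes lose PageRank in the tumor (`decreased`), a
small fraction gains score while losing degree (`relative_increase`,
the signature of becoming relatively central in a sparser network), and
oncogene-to-epigenetic-regulator shortest paths get longer on average
while more pairs become disconnected entirely — the planted
perturbation, recovered end to end.

`results` also carries the dual graph (`results.dual`), the per-gene
centrality table (`results.centrality`), community partitions,
raw path results, plotting helpers (`plot_degree_distributions`,
`plot_path_length_histogram`) and exporters for graph-database
bulk-import CSV and Cypher loader scripts.

The same run is available from the shell:

```bash
coexnet run-all --out run1 --seed 8
coexnet simulate --out fixture --seed 8
coexnet build --normal fixture/expression_normal.tsv \
              --tumor fixture/expression_tumor.tsv --out nets
coexnet analyze pagerank --normal-edges nets/edges_normal.tsv \
    --tumor-edges nets/edges_tumor.tsv \
    --annotation fixture/annotation.tsv --out pagerank.tsv
```

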