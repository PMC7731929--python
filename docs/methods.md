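# Methods

## Overview

`coexnet` builds matched normal/tumor weighted gene co-expression
networks from bulk expression matrices and quantifies how the tumor
network is perturbed relative to its normal counterpart. The analysis
has four layers: edge construction, graph algorithms, differential
statistics, and gene-set over-representation. A synthetic-data
generator with planted ground truth makes every layer testable without
external cohorts.

## Edge construction

Co-expression between two genes is measured by the Spearman rank
correlation ρ across samples (Pearson correlation of average fractional
ranks; ties get mean ranks, which matters because FPKM-like data
contains many tied zeros). Edges are produced by two rules applied to
each unordered gene pair:

1. **Discard rule.** Pairs with |ρ| > 0.99 are discarded. In FPKM data
   correlations in this range are artifacts of near-zero expression of
   both genes in nearly all samples, not biology.
2. **Soft-threshold retention.** The coefficient is raised to the sixth
   power, w = ρ⁶, and the pair becomes an edge iff w > 0.25 (strict).
   The even power maps strong negative correlation to a strong positive
   weight; the signed ρ is kept as an edge attribute.

Algebraically an edge survives iff 0.25^(1/6) ≈ 0.79370 < |ρ| ≤ 0.99.
Both comparisons are strict ("above"), and the discard rule is applied
to |ρ| because its rationale — spurious perfect correlation — concerns
magnitude. Genes with zero variance have undefined correlation and are
silently excluded (logged); genes retaining no edge are absent from the
condition's node set, so node counts reflect only connected genes.
The correlation matrix is computed by ranking each gene profile once
and taking the matrix product of the standardized rank matrix, which is
O(G²·n) and handles a few thousand genes in seconds.

## Graph algorithms

All three algorithms follow the scoring conventions of the Neo4j-style
graph engines commonly used for this kind of analysis.

**PageRank (unnormalized, weighted).** The fixed point of

    score(n) = (1 − d) + d · Σ_m score(m) · w(m, n) / S(m)

with damping d = 0.85, S(m) the total weight incident to m, and each
undirected edge acting as two directed edges. Scores are not normalized
to a probability distribution: every score is at least 1 − d, an
isolated node scores exactly 0.15, and when no node is isolated the
scores sum to the node count. This formulation is identified by
published per-gene score tables in which zero-degree genes score
exactly 0.15. Iteration starts from 1.0 and stops when the maximum
absolute change falls below 1e−7 (configurable; the fixed point, pinned
by a linear-system oracle test, is the contract rather than any
specific iteration count).

**Louvain.** Two-phase weighted modularity maximization at resolution
1: local best-gain node moves over a seeded shuffled sweep order (ties
toward the lowest community id, plus a split-to-singleton candidate),
then community aggregation, repeated until stable, followed by a
node-level refinement pass of the coarse solution. Because the greedy
sweep can converge to local optima requiring multi-node reassignment to
escape, two standard remedies are built in: deterministic multi-starts
(default 8; the first from singletons, the rest from seeded random
initial partitions) and a Kernighan–Lin escape pass (a sequence of best
single moves allowing temporarily negative gains, keeping the best
prefix; truncated after 30 unproductive steps and skipped above 2,000
nodes for cost reasons). The reported Q is always recomputed from
scratch on the final assignment. The heuristic is near-optimal on small
graphs (validated against exhaustive partition search) but carries no
optimality guarantee.

**Dijkstra shortest paths.** Default cost is 1 per edge, so length =
hop count; `inverse_weight` mode uses cost 1/w so strong co-expression
is cheap to traverse. Hop count is the default because path-length
summaries in this analysis are reported in whole genes, and using raw
correlation weights as costs would perversely penalize strong
co-expression. Absent or disconnected endpoints give infinite length.
Among equal-cost paths, the walk from the source prefers the
lexicographically smallest next gene, making reported paths
deterministic. Class-pair queries (e.g. all oncogene × epigenetic-
regulator pairs) reuse one single-source run per source gene.

**Scale-free diagnostic.** Degrees are binned logarithmically (10 bins),
converted to a density, and log₁₀-density is regressed on log₁₀-degree;
the fit R² and slope are returned. At least five distinct degree values
are required. A preferential-attachment-like topology yields high R²
with negative slope; the diagnostic mirrors the soft-thresholding
rationale that powered weights induce approximate scale-freeness.

## Differential statistics

- **Size collapse**: node and edge fold changes, defined normal/tumor so
  values above 1 mean tumor loss.
- **Lost class edges**: normal-only edges joining two annotation classes
  (e.g. transcription factor–oncogene); symmetric in class order.
- **Centrality shift**: per-gene categories — `decreased` (PageRank
  lower in tumor), `relative_increase` (PageRank up, degree down),
  `absolute_increase` (PageRank up, degree not down), `unchanged`
  (exactly equal — measure-zero with floating scores). Computed over
  the union of both conditions' node sets; a gene absent from one
  subnetwork carries degree 0 and the 0.15 base score there.
- **Cross-network correlation**: Pearson r of per-gene score vectors for
  every within-group network pair over pairwise-complete shared genes
  (genes absent from a network are excluded, not zero-filled, since
  zero-filling would fabricate correlation), then a Welch two-sided
  t-test comparing the groups' r values with an explicit exclusion
  list for pairs that should not enter (e.g. two normal networks from
  the same tissue).
- **Recurrent degree gain**: genes with degree_tumor > degree_normal in
  at least `min_types` cohorts.
- **Community degree change**: distribution (median, quartiles) of
  per-gene degree change within each tumor community of at least
  `min_size` members (default 50).
- **Path perturbation**: per-condition mean over finite class-pair
  shortest paths, infinite-path counts, and the joint (L_normal,
  L_tumor) histogram with its modal transition over pairs finite in
  both conditions.

## Over-representation analysis

Community membership is unranked, so enrichment is the upper-tail
hypergeometric probability P(X ≥ k) of the observed overlap k between a
community (size n) and a gene set (size K) in a universe of N genes.
The universe is the intersection of the analysis namespace with the
collection universe — the standard conservative choice; when the
full measured namespace is known it can be passed explicitly to widen
the collection universe. Benjamini–Hochberg correction is applied per
community across sets. Communities below the minimum size (default 50
genes) are skipped.

## Synthetic matched cohorts

The generator emulates FPKM-like matched normal/tumor matrices with a
latent-factor log-normal model: a gene in module m with loading a has

    log x = a · f_m + (1 − a) · σ · ε,   f_m, ε ~ N(0, 1) i.i.d.

with noise scale σ (`noise_sd`, default 2.0). Values are positive and
right-skewed, and because Spearman correlation is invariant to the
exponential transform, the within-module rank correlation is
analytically controlled: the log-scale Pearson correlation is
a²/(a² + (1−a)²σ²), e.g. ≈ 0.97 at a = 0.92, σ = 2 — inside the
(0.794, 0.99] retention band, so planted modules become near-cliques
without tripping the artifact-discard rule. Loadings are restricted to
[0, 1): a loading of 1 would force |ρ| > 0.99 and every module edge
would be discarded. Background genes are pure noise and therefore
absent from the network at realistic sample counts.

The tumor matrix redraws all latent variables (matched samples, new
factor realizations) and applies three perturbations:

- **Dissolution**: a fraction of modules (default 0.4) become background
  noise — their genes drop out of the tumor network, collapsing node
  and edge counts.
- **Rewiring**: a fraction (default 0.1) of intact-module genes follow a
  different intact module's factor in the tumor, restructuring
  communities.
- **Gained hubs**: background genes (default 30) acquire tumor-only
  connectivity through a shared tumor-specific program with graded
  activation — hub i loads on cos(θᵢ)·h₁ + sin(θᵢ)·h₂ with θ increasing
  linearly from 0 to π across hubs. Nearby hubs correlate strongly,
  distant hubs weakly, so the tumor gains a connected band-like
  component whose internal shortest paths span several hops. A single
  shared factor would instead create a clique (all paths length 1);
  the graded variant also reproduces the lengthening of finite
  class-pair paths seen when comparing tumor to normal networks.

Class labels (transcription factor, epigenetic regulator, oncogene) are
allocated by stratified largest-remainder sampling across modules and
background: per-class totals equal round(fraction × n_genes) exactly,
and every planted module carries members of each class so class-pair
statistics are always defined. Default fractions (0.08, 0.10, 0.10)
are enriched relative to genome-wide rates to populate class-pair
statistics at desk scale (2,000 genes). Defaults elsewhere emulate a
matched cohort at desk scale: 2,000 genes × 60 paired samples, five
40-gene modules at loading 0.92.

What the generator does **not** model: read counts and library-size
normalization, batch effects, tissue heterogeneity, dropout, gene
length bias, and correlated background structure. Passing tests
demonstrate that the pipeline recovers planted structure under this
generative model; they do not certify performance on real cohorts,
where weaker and hierarchically overlapping modules, confounders and
smaller effect sizes all matter.

## Numerical choices and degenerate inputs

- Spearman of a constant vector is NaN (gene excluded), not an error;
  fewer than 3 samples is an error.
- Edge weights are validated as w = ρ^power to 1e−9 on construction and
  file round-trips write full `repr` precision so read-back is exact.
- PageRank requires strictly positive weights and 0 < d < 1.
- Modularity is undefined (error) for graphs with no edges; Louvain
  requires at least one edge. Modularity gains are accepted only beyond
  1e−12 to avoid cycling on floating-point noise.
- Dijkstra uses a 1e−12 tolerance when comparing accumulated
  inverse-weight costs during path reconstruction.
- Fold changes for an empty tumor subnetwork are +inf with a warning.
- All randomness (generator, Louvain sweep order and restarts) flows
  from explicit integer seeds; identical seed + config reproduce
  byte-identical artifacts, and the pipeline manifest records the seed.

## Problem sizes used in the test suite

The end-to-end recovery suite runs the default-scale cohort (2,000
genes × 60 samples, five 40-gene modules, two dissolved); unit and
oracle suites use graphs of up to 50 nodes (PageRank linear-system
oracle), 10 nodes (shortest-path enumeration), and 8 nodes (exhaustive
modularity search). These sizes were chosen so the exact oracles stay
exact and the whole suite completes in minutes.

## Known limitations

- Louvain is a heuristic; near-optimality is validated only at small n.
- The unnormalized PageRank convention is not comparable across graphs
  of different size without rescaling (scores sum to n).
- The hypergeometric universe choice materially affects p-values; the
  conservative intersection default can differ from published analyses
  whose universe is unstated.
- Only Spearman co-expression is implemented (no Pearson or mutual-
  information alternatives, no topological overlap).
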