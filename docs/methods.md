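# Methods

## Overview

`knemap` compares transcriptomic exposure profiles through a knowledge-driven
network mapping. Instead of comparing exposures gene by gene, genes are first
organized into similarity communities on a *prior network* fused from several
prior-knowledge layers, and each exposure is summarized by how its most
deregulated genes distribute over those communities. The package implements
the full pipeline, three baseline representations, the benchmark and
robustness experiments used to compare them, and a seeded synthetic-data
module that emulates every input at desk scale.

## Prior-knowledge layers

Two kinds of raw input become weighted gene–gene similarity layers:

* **Evidence edges** (e.g. protein–protein interactions): the weight of a
  gene pair is the number of distinct data sources supporting the edge.
* **Association sets** (e.g. gene–disease, gene–pathway): two genes are
  connected iff they share at least one entity, weighted by the shared-entity
  count. Genes sharing nothing remain as isolated nodes so layers over the
  same universe stay comparable. Raw shared counts are used rather than a
  size-normalized overlap (e.g. Jaccard of entity sets); the count is the
  natural evidence unit here and downstream scaling removes the layer scale.

Layer weights are scaled into (0, 1] by dividing by the layer maximum.
Division by the maximum (not min–max) preserves weight ratios and never maps
a real edge to 0, which would be indistinguishable from an absent edge. The
operation is idempotent and order-preserving.

## Layer fusion

Layers are merged hierarchically, guided by how similar their *binary* edge
sets are:

1. **Layer distance.** For each layer pair, with the universe U equal to the
   union of edges over all layers: Jaccard distance 1 − |∩|/|∪|; simple
   matching coefficient distance 1 − matches/|U| (matches = both-present +
   both-absent over U); and a shared-edge-fraction distance
   1 − |∩|/min(|E_i|, |E_j|). The SMC universe is the observed edge union,
   not all gene pairs — over all pairs the score is dominated by shared
   absences and adds no information at realistic sparsity. The
   shared-fraction denominator is `min` by default (containment of the
   smaller layer); `mean` and `union` are available via
   `shared_fraction_denominator` since with `union` the component duplicates
   Jaccard. The three components are summed with equal weight and min–max
   scaled over the off-diagonal entries into [0, 1].
2. **Layer clustering.** Ward hierarchical clustering of the distance
   matrix, cut to `k` clusters (default 3, configurable). Layers are ordered
   lexicographically by name before clustering so ties resolve
   deterministically.
3. **Two-stage merge.** Within each cluster, every layer's weights are
   rescaled to a common median (`target_median`, default 0.5 — the midpoint
   of the weight range; only relative weights matter downstream) and summed
   edge-wise; each cluster network is scaled to (0, 1] by its maximum. The
   cluster networks are then merged the same way, and the final weights are
   again divided by the maximum, giving the fused prior network with weights
   in (0, 1]. The merge tree, target median and scaling constants are kept
   in the provenance record.

## Community detection

Gene communities come from agglomerative clustering on the prior network's
pairwise distances: 1 − weight for connected pairs, 1.0 (the maximum) for
unconnected pairs, cut at a distance threshold (default 0.5). The linkage is
configurable (`single`, `average`, `complete`) with **single** as default.
This choice was made empirically: on fused networks whose weights are
max-scaled (and therefore carry a heavy right tail, with typical edge
weights well below 1) and whose absent edges saturate at distance 1,
average and complete linkage stall long before coherent similarity groups
are assembled, fragmenting planted modules into pairs and triples; single
linkage follows the strongest similarities through a group while the
threshold blocks chaining across groups, and recovers planted modules
essentially perfectly (adjusted Rand index ≥ 0.94 on the default synthetic
conditions). On very dense, high-weight networks single linkage can chain;
the `linkage` option exists for that regime.

The dense distance matrix is materialized; the package targets universes up
to a few thousand genes.

## Exposure fingerprints

Per exposure (compound × biological system) the genes are scored by

    FCP = logFC × (−log10 p)

(p-values floored at 1e−300; the log base is configurable — it changes FC
vector magnitudes but no ranking). After restricting to genes present in
the prior network, the 100 most positive and 100 most negative FCP genes
are selected; ties break by |logFC| then symbol, and a side with fewer
qualifying genes contributes fewer — zero-FCP genes never pad the
selection. Four representations are built from the same selection:

* **Community fractions** (the package's own fingerprint): fraction of the
  selected genes in each community; spans all communities and sums to 1.
* **BDG**: binary indicator of the selection over the measured-gene universe.
* **FC**: raw FCP values over a fixed common gene ordering.
* **GSEA**: preranked gene-set enrichment p-values of the selection against
  every other exposure's FCP-ranked list in the same system (self excluded,
  references ordered by exposure id). The enrichment is a weighted
  Kolmogorov–Smirnov running sum: hits increment by |FCP|^w normalized over
  the set (w = 1 by default; if all set members carry zero FCP the
  unweighted 1/n step is used), misses decrement by 1/(N − n), ES is the
  signed maximum deviation, and significance comes from gene-label
  permutations with p = (1 + #{|ES*| ≥ |ES|})/(1 + n_perm). The
  implementation is from scratch and vectorized over permutations; n_perm
  defaults to 1000 for standalone use, and the benchmark context uses 300
  as a balance between p-value resolution and runtime.

A Welch two-sample t-test on replicate expression values (logFC = mean
difference on log-scale data, p two-sided, degenerate zero-variance genes at
p = 1) stands in for a full linear-model differential-expression fit so the
noise and stability experiments run end to end.

## Benchmarks

* **Similarity matrices**: pairwise cosine distance or Pearson correlation.
  A zero vector is at distance 0 from another zero vector and 1 from any
  non-zero vector, so degenerate vectors cannot produce NaNs inside loops.
* **Compound clustering**: Ward on cosine distances, cut at k; cross-system
  comparison via the Jaccard matrix between cluster member sets, a best
  match per cluster, and the consistent exposure set at J ≥ 0.5 (threshold
  configurable).
* **Class retrieval**: for each labeled compound the others are ranked by
  Pearson similarity; score at x = same-class compounds in the top x divided
  by the class size excluding the query itself (a compound cannot retrieve
  itself; singleton classes contribute 0); curves are summed over compounds
  and compared by trapezoidal AUC, with a mean curve across systems.
* **Structural rank agreement**: all exposure pairs ranked by cosine
  distance are compared with a reference ranking from Levenshtein distances
  on structure strings (or cosine distances on descriptor vectors); ties get
  average ranks. Two curves: mean absolute rank difference over the
  method's top x (2..200; absolute differences — the sign is not
  informative for agreement) and the Jaccard index of the top-x sets
  (1..1000), both with trapezoidal AUCs and grids truncated to the number
  of pairs.
* **Gaussian noise**: additive N(0, σ²) noise on every expression entry over
  σ ∈ {0.01, 0.1, …, 1}, profiles and vectors recomputed per level, and the
  mean cosine distance of each exposure to its noise-free baseline reported
  per level with an AUC per method. Levels are coupled by common random
  numbers: one standard-normal field Z is drawn from the seed and the
  level-σ perturbation is σZ. Each level still receives exact N(0, σ²)
  noise, but comparisons across levels isolate the noise magnitude from
  resampling variance, which at desk scale (tens of exposures rather than
  hundreds) would otherwise dominate the level-to-level differences of the
  GSEA curves.
* **Replacement noise**: each selected gene is replaced with probability p
  by a uniformly drawn universe gene not currently in the selection (so the
  selection size is conserved and high p is never a silent no-op), vectors
  rebuilt, distances to baseline summarized as above; per-level child seeds.
* **Subset stability**: genes differentially expressed between control
  samples of any system pair (Welch, p < α = 0.05) are removed; fingerprints
  recomputed on the stable subset are compared with full-universe ones via
  the distribution of per-exposure-pair cosine-distance differences.
* **Cross-dataset matching**: with both datasets fingerprinted against the
  same partition, candidates are ranked by cosine distance per
  (query-system, candidate-system) combination; a candidate's mean rank
  across combinations scores it and the minimum (ties by id) is the best
  match.

All AUCs are trapezoidal on the stated grids without normalization.

## Synthetic data

The generator plants recoverable structure at a scale where the full
pipeline runs in minutes on one CPU while keeping the qualitative regime of
the real application (many small communities; compound groups separable
within a biological system but not across systems):

* 300 genes in 20 blocks; 6 layers sampling intra-block edges at 0.6 and
  inter-block at 0.01 with integer weights 1–3 emulating evidence counts;
* 30 exposures in 3 groups on 2 systems, 3 replicates, additive N(0, 1)
  measurement noise on a log-like scale, group signatures of 3 blocks
  shifted by ±4 (signal-to-noise 4) with per-system multipliers in
  U(0.5, 1.5) and 30% sign flips so groups cohere within but not across
  systems, plus mild per-exposure magnitude jitter;
* class labels equal to the planted groups (optional label noise) and
  structure strings with a shared group prefix so within-group edit
  distances are smaller in expectation.

Alongside the replicate matrices the generator emits exact noise-free
profiles: logFC is the planted shift and the p-value is the expected
two-sided normal tail of that shift at the configured replicate count and
noise level.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, realistic chemistry in the structure strings, and the highly
skewed community-size and density profile of a real fused knowledge
network. Passing tests therefore show that the pipeline's operations are
correct and that its qualitative claims (noise robustness of the community
fingerprint, within-system group coherence, stability to steady-state
differences) hold under controlled conditions — not that they hold at the
scale or messiness of real compendia.

## Numerical choices and degenerate inputs

* p-values clamped to [1e−300, 1]; NaN p-values from zero-variance Welch
  tests become 1.
* Community and cluster labels are relabeled 0-based in order of first
  appearance, so partitions are deterministic given the input.
* Merging ties in hierarchical clustering follow the backend's
  deterministic order after lexicographic input ordering.
* If all off-diagonal layer distances are equal, the min–max scaled matrix
  is all zeros (the layers are indistinguishable at the binary level).
* Empty selections produce all-zero fingerprint vectors; zero-vector cosine
  rules above then apply.

## Known limitations

* The dense distance matrix in community detection is O(n²) memory.
* GSEA permutation p-values have resolution 1/(n_perm + 1); vectors built
  with small n_perm quantize.
* The Welch stand-in has no empirical-Bayes moderation, so its p-values on
  2–3 replicates are noisier than a moderated fit would give; the planted
  effect sizes compensate at default conditions.
* Single-linkage community detection can chain on very dense high-weight
  networks; switch `linkage` if the weight distribution is not
  heavy-tailed.
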