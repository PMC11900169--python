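# Methods

## Overview

`coexdiff` infers one co-expression network per phenotype group from
RNA-seq counts and compares the two networks at three scales: global
topology, individual central genes, and modular (mesoscopic) organization.
Edges encode statistical dependence of expression across samples, measured
by mutual information so that monotone and non-monotone relationships count
alike; no direction or mechanism of regulation is implied, and the networks
are strictly undirected.

## Preprocessing

Genes are kept when their mean counts-per-million across all samples is at
least 1 (a per-sample variant, `min_samples_over_cpm`, is available). TMM
scaling factors follow Robinson–Oshlack: per sample against a reference
(the sample whose upper-quartile CPM is closest to the mean of upper
quartiles), log2 ratios M and mean log2 abundances A are computed on genes
positive in both, symmetric rank trimming removes the most extreme 30% of M
and 5% of A on each side, and the factor is 2 to the weighted mean of the
surviving M values with inverse-asymptotic-variance weights
(N−y)/(Ny) summed over the two samples. Factors are re-centered to
geometric mean 1. Normalized values are count/(library·factor)·1e6,
optionally divided by gene length in kb when lengths are supplied (length
adjustment is independent of the TMM factors and off by default). The
matrix is filtered and normalized as a whole and stratified afterwards, so
both condition matrices share one gene universe. Batch correction is a
deliberate no-op hook: the synthetic data generate no batch structure, and
noise-removal methods are out of scope.

## Network inference

Each gene is discretized independently. The default is equal-frequency
binning with ⌈n_samples^(1/3)⌉ bins: samples are ranked (stable order on
ties) and assigned to balanced rank blocks whose occupancies differ by at
most one; a constant gene falls entirely into bin 0. Equal-width binning is
available. Bin count and method only shift the MI scale, and only the rank
order of pair values matters for percentile thresholding, so these choices
are far less consequential than they appear; both are exposed in the
config.

Pairwise MI uses the plug-in (maximum-likelihood) estimator in nats,
computed for all pairs via the identity MI = H(x) + H(y) − H(x,y) with
joint histograms accumulated through one matrix product per bin pair —
results are exactly independent of the internal chunking. Pairs involving
a constant gene contribute MI = 0.

The network keeps the top k = ⌊(100 − P)/100 · N_pairs⌋ pairs at
percentile P (default 99.99). Ranking is by MI descending with boundary
ties broken by lexicographic gene-pair order, so the build is fully
deterministic and two condition networks over the same gene universe always
have identical edge counts — which makes their topology directly
comparable. k is computed as ⌊round((100−P)·N/100, 9)⌋ to protect the
exact-k contract from floating-point noise when the tail fraction times N
is integral. A percentile sweep (99.9999 … 80) reports nodes, edges,
components, largest component, and transitivity per candidate threshold.

The permutation null shuffles every gene's sample order independently,
which destroys all between-gene dependence while preserving marginals, and
recomputes the MI percentile on a fixed random subsample of at most 1e5
pairs per permutation. The empirical p is the fraction of null thresholds
reaching the observed one. A second, graph-level null (degree-preserving
double-edge swaps) lives in the topology module for transitivity and
diameter.

## Topology

The scaling exponent γ is the negated slope of an ordinary least-squares
fit of ln p(k) on ln k over degrees with nonzero frequency — the
log-log-histogram reading of the degree distribution. Maximum-likelihood
fits of candidate distributions (discrete power law / Zipf with support
k ≥ 1, Poisson, geometric, negative binomial, and normal on log-degree with
the Jacobian included so likelihoods are comparable) are ranked by
AIC = 2·n_params − 2·loglik. Betweenness is unnormalized shortest-path
betweenness (each unordered pair counted once, equal-length paths sharing
fractionally). Hubs and high-betweenness genes are the top 10% by the
respective score; genes tied with the boundary score are all included, so
the set size can exceed ⌈0.1·n⌉ under ties. Diameter on a disconnected
graph is the maximum finite shortest-path length (largest within-component
eccentricity). Set comparisons report percentages relative to the union of
the two sets.

## Communities

Partitions minimize the two-level map equation for an undirected graph:
node visit rates are degree-proportional (strength-proportional in the
weighted variant), module exit rates come from inter-module edge mass,
logarithms are base 2, and the returned L is bits per random-walk step.
The optimizer is a greedy descent: starting from singleton modules it
alternates local node moves — each scored by the exact change in L
maintained through module aggregates — with module-merge passes, until no
step lowers L; this repeats over `n_trials` random node orders, the
single-module and connected-component partitions are always evaluated as
deterministic baselines, and the lowest-L labeling wins. Descent is
monotone within a trial and the whole procedure is deterministic given the
seed. On every connected graph small enough to enumerate all set
partitions, the optimizer attains the global minimum (verified
exhaustively in the test suite over hundreds of graphs up to 7 nodes); on
larger planted-structure benchmarks it recovers the planted modules
exactly. Graphs are unweighted by default for both L and Q, since edges
are already thresholded "significant co-expression" relations; MI-weighted
variants are a config switch.

Newman modularity is computed per module as e_c/m − (d_c/2m)², and the
contributions sum exactly to the global Q. NMI between partitions is the
plug-in mutual information of the label contingency table normalized by
the arithmetic mean of the label entropies (max/min/joint normalizations
available); partitions over different node sets are compared on the
intersection. Module-membership similarity is the full Jaccard matrix
between the two partitions' modules, summarized by greedy one-to-one
matching (highest Jaccard first) and preservation counts at thresholds
1.0 … 0.5. Module ids are contiguous and ordered by decreasing size.

## Enrichment

Over-representation uses the upper-tail hypergeometric test
p = P(X ≥ n_overlap), X ~ Hypergeom(N = |universe|, K = n_term,
n = |query|), with Benjamini–Hochberg q-values over all tested terms and a
dual cutoff p ≤ 0.05 and q ≤ 0.05. The background universe defaults to all
genes in the annotation universe (typically every post-filter gene), not
only network nodes, because network membership is itself
outcome-dependent; a different universe can be passed explicitly.
Annotations are used exactly as given in the GMT — no ontology-ancestor
propagation — so synthetic tests have exact control over term content.
Functional similarity between modules is the Jaccard index of their
enriched-term sets; modules with no enriched terms yield NaN (flagged
empty) rather than a conventional zero. Process representation counts, per
term, how many modules of each condition are enriched for it and sorts by
the absolute difference.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:

- **Marginals.** Negative-binomial counts with gene means drawn
  log-uniformly from `nb_mean_log_range` (default (1, 5) on the natural
  log scale, i.e. means ≈ 3–150) and common dispersion 0.2 — typical bulk
  RNA-seq values. Per-sample depths are uniform on `library_size_range`
  (default 0.8–1.2e6, applied as relative depth factors).
- **Dependence.** A Gaussian copula: each planted module has one shared
  standard-normal factor per sample; a member gene's latent is
  √ρ·factor + √(1−ρ)·noise, so the within-module latent correlation is
  exactly ρ (default 0.8). Latents pass through the NB quantile function,
  giving monotone but non-linear dependence between counts — the regime
  where MI has an advantage over linear correlation.
- **Rearrangement.** In condition B, ⌊f·s⌋ genes per module (seeded random
  choice) are reassigned round-robin to the other modules. For equal
  module sizes s this keeps all module sizes at s and makes the
  best-match Jaccard between the two planted partitions exactly
  (s−r)/(s+r) with r = ⌊f·s⌋ — a closed form the tests and the acceptance
  script check against.
- **Hubs.** `n_hubs_b` background genes load, in condition B only, on
  ⌈n_modules/2⌉ module factors at weight √(ρ/⌈n_modules/2⌉) each —
  moderate correlation to many modules rather than strong correlation to
  one.
- **Annotations.** One "true" term per planted module containing a
  coverage-fraction subset of its genes, plus decoy terms of random genes
  with matched sizes.

What the generator does **not** emulate: batch effects and library
composition bias (an optional additive group shift exists but is off by
default), clinical covariate structure, length-dependent counting bias,
and the heavy right tail of real dispersion estimates. Passing tests
therefore demonstrate correctness of the algorithms and calibration of the
statistics under the stated model, not robustness to every artifact of
real tissue data.

## Benchmark conditions and problem sizes

The standing benchmark is 2,000 genes, ten modules of 50, ρ = 0.8, 150
samples per condition, 20% rearrangement, five hubs, seed 42. At this
universe (≈2e6 gene pairs) the study-scale 99.99th percentile would keep
only ~200 edges — far below the 12,250 planted within-module pairs — so
benchmark networks are thresholded at the 99.5th percentile, whose ~10k
retained edges match the planted edge mass; the pipeline default for real
data remains 99.99. Null-model calibration uses a 500-gene, ρ = 0
design with 30 permutations; enrichment type-I calibration uses 100 random
queries of 150 genes against 60 random terms sized 50–500 on a 2,000-gene
universe (term sizes chosen so the discrete hypergeometric test's
attainable level is near the nominal 0.05; the measured rate is slightly
conservative, as expected for a discrete test). The end-to-end determinism
check runs a 150-gene pipeline twice and compares report hashes.

## Numerical choices and degenerate inputs

- MI is clipped at 0 to absorb rounding; `mutual_information` canonicalizes
  its argument order so mi(x,y) and mi(y,x) are bit-identical.
- A constant gene has H = 0 and MI = 0 with everything; such pairs are
  never retained at high percentiles.
- γ fitting requires ≥ 3 distinct degrees; uniform-degree graphs raise an
  error rather than returning a meaningless slope.
- `top_fraction` on an all-tied score vector returns every gene (documented
  degenerate case of boundary-tie inclusion).
- NMI of two trivial (single-module) partitions is defined as 1; values
  within 1e-12 of 0 are returned as exactly 0.
- All randomness flows from explicit seeds; the pipeline derives per-stage
  seeds as CRC32(seed:stage) < 2³¹ so rerunning one stage never perturbs
  another.

## Known limitations

- The map-equation optimizer is two-level only (no hierarchical modules)
  and greedy; global optimality is guaranteed only where verified by
  enumeration, though restarts plus merge passes recover planted structure
  reliably at benchmark scale.
- The plug-in MI estimator is positively biased at small sample sizes;
  this bias is shared by all pairs and largely cancels under rank-based
  thresholding, but absolute MI values should not be compared across
  sample sizes.
- Betweenness and diameter are exact and thus quadratic-plus in component
  size; very large dense networks would need approximation.
- Enrichment treats annotation terms as flat sets; semantic similarity
  between terms and ontology structure are out of scope.
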