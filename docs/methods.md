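# Methods

## Skeleton learning

The learner recovers an undirected dependency skeleton among p taxa from an
n × p count table. All information measures assume a joint Gaussian model
on the (transformed) abundances: MI and CMI are computed from sample
covariances (n − 1 denominator, natural logs, units nats), so
MI = −½ log(1 − ρ²) for the sample correlation ρ, and order-1 CMI equals
−½ log(1 − ρ²_{XY·Z}) for the partial correlation given a single
conditioning taxon. The Gaussian form is a working assumption: it captures
monotone dependence after a variance-stabilising transform, but genuinely
non-monotone relationships are invisible to it.

Stages, in order:

1. counts are transformed (default: log(count + 1); see Normalisation);
   constant taxa are dropped with a warning, since their (C)MI is
   undefined;
2. MI is computed for all p(p−1)/2 pairs from a single covariance matrix;
3. edges strictly below the empirical q1 quantile (linear interpolation
   between order statistics) of all pairwise MI values are removed → S0.
   Ties at the threshold are kept: removal requires being clearly under
   the threshold;
4. for every S0 edge (X, Y), candidate separators are fixed once as the
   common neighbours of X and Y in S0; CMI(X, Y | Z) is evaluated per
   single separator and the maximum kept (ties between separators broken
   toward the lexicographically first, which does not affect the edge
   decision);
5. edges strictly below the q2 quantile of the max-CMI values are removed
   → S1. The q2 distribution is computed only over edges that have at
   least one separator; edges with no common neighbour have no
   conditioning evidence that could explain them away and are retained,
   bypassing the filter. (An alternative would pool separator-less edges
   into the distribution at their MI value; we prefer the bypass because
   it never removes an edge on evidence that was never computed.)

Freezing separator sets from S0 before any removal is what makes the
output invariant to the order in which taxa are presented; the test suite
includes a deliberately order-sensitive variant (sequential removal with
recomputed neighbourhoods) as a regression contrast. Inference contains no
randomness.

**Parameters.** q1 (default 0.70) and q2 (default 0.95) directly control
sparsity: each is a quantile in (0, 1), and higher values give sparser
skeletons, monotonically. For benchmarking against a known ground truth,
`tune_q2_to_edge_count` bisects q2 until |S1| is closest to the target
edge count (ties to the sparser network) — the natural way to compare
methods at matched density when no labelled validation set exists to
optimise q1/q2 directly.

**Numerical policy.** Degenerate covariances (duplicated taxa, near-exact
collinearity) get a ridge of 1e-10 · trace/dim before determinants are
retried; if the determinant ratio still diverges the value is capped at 10
nats with a warning (an effectively infinite MI carries the same message
for edge ranking). Values in (−1e-9, 0) from floating-point roundoff are
clamped to 0; anything below −1e-9 raises, since a genuinely negative
estimate signals a bug rather than roundoff.

## Normalisation

Four sample-wise transforms are provided: log(count + c), CLR
(log(count + c) minus the per-sample mean of those logs), TSS (divide by
the sample total), and GMPR (divide by the sample's size factor: the
geometric mean over other samples of the median pairwise count ratio,
restricted to taxa nonzero in both). The pseudocount c defaults to 1 and
is configurable; results are mildly sensitive to it for low-count taxa,
which is one reason the pairwise normalisation comparison exists. A sample
sharing no nonzero taxon with any other sample has no defined GMPR factor
and errors out rather than silently receiving factor 1. Log is the
inference default as a pragmatic variance stabiliser; CLR additionally
addresses compositionality and can be supplied externally with
`quantitative=False`.

## Consensus

Inputs are binarised, unsigned networks on an identical node set (node-set
mismatches are an error rather than being silently unioned, because they
almost always indicate inconsistent upstream filtering). Simple voting:
weight(i, j) = number of methods containing the edge, 0..M. Thresholding
at ≥1 … =M trades density against unanimity; the Venn-cell partition
(`edge_overlap_partition`) reports the exact per-subset counts. Signed
outputs (correlation-based methods) must be binarised upstream — the
consensus deliberately records only the presence of a strong association,
not its sign, because MI/CMI-based edges are inherently unsigned.

## Bootstrap reproducibility

Reference = network from the full table. Each of n_boot (default 50)
replicates resamples n rows with replacement (replicate r uses an
independent RNG stream seeded seed + r, so different methods can share the
identical resamples for paired comparison), re-infers, and is scored
against the reference by precision/recall/F1 and Jaccard on edge sets.
Convention: two empty networks score 1 on all metrics; one-empty scores 0.
The F1 distribution is summarised by median, sd and the 95% percentile
interval (θ*₀.₀₂₅, θ*₀.₉₇₅). These quantify stability under resampling,
not correctness. Paired per-replicate F1 distributions are compared with
the two-sided Wilcoxon signed-rank test; with more than one comparison,
p-values are Holm-adjusted (chosen as conservative and assumption-free;
the adjustment is configurable).

## Taxon selection

**ML.** Seven rankers each keep k = ⌈0.2 p⌉ taxa: SelectKBest on the
one-way F statistic and on nonparametric label MI, RFE down to k features
driven by logistic-regression coefficients, decision-tree, gradient-
boosting and random-forest importances, and an abundance filter keeping
taxa whose per-taxon maximum reaches the (1 − 0.2) quantile of the maxima
(interpreted this way because a "top 20% of the dataset" rule is only
well-defined per taxon statistic; ties at the quantile boundary are all
kept). Hyperparameters are pinned (logistic: L2, C = 1; forest/boosting:
100 estimators; tree: unrestricted) — defensible defaults rather than
tuned values, recorded so runs are reproducible. TOTAL(taxon) = number of
selecting methods within one normalisation; the headline set uses the log
normalisation's TOTAL with the majority-rule cutoff TOTAL > 3, and the
cross-normalisation intersection flags preprocessing-robust taxa.

**Network.** Five centralities per network: degree (raw count),
eigenvector (per connected component, power iteration tol 1e-10, isolated
nodes 0), PageRank (damping 0.85), harmonic closeness normalised by n − 1
(finite on disconnected graphs, which real condition-specific networks
frequently are), betweenness normalised by (n−1)(n−2)/2. Strategy 1 ranks
taxa per method and metric by |centrality(clean) − centrality(scab)|,
flags the top ⌈0.2 p⌉ in any metric for that method (union across
metrics, so the report can name the responsible metrics), and intersects
across methods. Strategy 2 min–max scales each metric within a network —
without scaling, whichever metric has the largest raw range would dominate
the weighted sum regardless of the weights — and combines them with
weights (0.1, 0.1, 0.1, 0.2, 0.5) for (DE, EV, PR, CL, BE), weighting the
path-based family highest because bridging taxa are the usual keystone
candidates; the per-condition consensus intersects the top sets across
methods. Metrics whose range is within numerical noise (≤ 1e-9 relative)
contribute 0 rather than amplifying power-iteration jitter. Boundary ties
are always included, with a warning, so selection is deterministic and
label-independent. The final report intersects ML with the network
strategies (`intersection_all`, or `ml_and_any_network`) and emits the
tier table (ML∩S1∩S2, ML∩S1, ML∩S2, S1∩S2).

## Synthetic data

The generator emulates sparse, structured dependence in zero-rich
overdispersed counts. Ground truth: band graph (edge iff index distance ≤
band width); precision matrix with ±strength (default 0.3, signs seeded)
on edges and diagonal = absolute row sum + 1 (strict diagonal dominance ⇒
positive definite, support exactly the adjacency). Counts: NorTA — latent
MVN with the implied correlation, pushed through Φ and the inverse CDF of
a zero-inflated negative binomial (defaults mean 20, dispersion 0.5,
zero probability 0.3; dispersion is the NB size, so variance =
mean + mean²/dispersion and large values approach Poisson). These defaults
give roughly 40% zeros and variance ≈ 40× the mean, in the range typical
of genus-level OTU tables. `two_class_dataset` shares a seeded core of
round(shared_frac · m) band edges between conditions and rewires the rest
to disjoint off-band pairs, keeping both class graphs at m edges, so the
edge Jaccard between the class truths is s/(2 − s) by construction.

What the generator does *not* emulate: compositional closure from
sequencing depth, taxon-specific marginals fitted to a real template,
phylogenetic correlation of abundances, or sample covariates. Passing
tests therefore demonstrate correct recovery of copula-Gaussian band
structure at desk scale, not performance on any particular real survey.

## Problem sizes and baselines

The end-to-end benchmark uses p = 50, band width 2 (97 true edges),
n = 300 samples, with q2 tuned to the true edge count; the acceptance
script's bootstrap uses p = 30, n = 150, 50 replicates; the selection
pipeline uses p = 20, 150 samples per class, shared_frac 0.5. The random
baseline for recovery is the closed-form expected F1 of a uniformly random
network at matched density, E[F1] = 2km / (N(m + k)) for m true and k test
edges among N pairs; the tuned skeleton exceeds 3× this baseline by a wide
margin (≈ 7× at the benchmark settings).

## Known limitations

- The Gaussian closed form measures only the dependence visible in
  (transformed) covariances; strongly non-monotone interactions are missed.
- No compositionality correction is built into inference itself; CLR input
  is the recommended mitigation.
- Conditioning is order-1 only (single separators); densely confounded
  triples with multi-taxon mediation can leave indirect edges in place.
- Edge signs are deliberately discarded throughout, so cooperative and
  competitive associations are indistinguishable in the outputs.
- Bootstrap F1 measures reproducibility; a method can be stably wrong.
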