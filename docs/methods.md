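# Methods

This note documents the models implemented in `netvgk`, the synthetic-data
generator that exercises them, the numerical conventions, and the design
choices made where the underlying methodology leaves room.

## Co-expression networks and cohesion

Networks are built per outcome group on a chosen gene set (by default the
top-variance genes) with an edge wherever the absolute Pearson correlation
across that group's samples strictly exceeds 0.6. The graph is simple,
unweighted and unsigned; isolated genes stay in the node set so a knockout
is defined for every selected gene. Correlations are computed on the stored
(log-scale) values; constant genes are an error and must be filtered
upstream.

Cohesion is the arithmetic mean of edge density `2m/n(n-1)` (0 when n < 2)
and the global, transitivity-style clustering coefficient
`3 x triangles / connected triplets` (0 when the graph has no connected
triplets). Both terms lie in [0, 1]. Note the triplet convention makes
cohesion of a 2-clique 1/2, not 1: a two-node graph has no clustering to
speak of.

## Virtual gene knockout and differential impact

The knockout impact of gene v is `cohesion(G) - cohesion(G - v)`; negative
impacts are legal (removing a pendant vertex can raise both density and
clustering). `knockout_impact` recomputes cohesion on the deleted graph;
the all-genes table used by `differential_impact` instead updates the
triangle and triplet counts incrementally (removing v subtracts the
triangles through v, `C(d_v, 2)` triplets centered at v, and one wedge per
neighbor edge), which reduces the whole table to a single sparse
matrix product. The two routes are held equal to 1e-9 by the test suite's
brute-force enumeration oracle on random small graphs and on generated
cohort networks.

DI = impact in the non-healed network minus impact in the healed network,
ranked descending with lexicographic tie-break. Genes present in only one
network are excluded and reported separately rather than imputed at zero
impact, which would silently distort ranks.

PageRank perturbation computes the stationary distribution before and
after node deletion by power iteration (damping 0.85, L1 residual < 1e-12,
dangling nodes teleport uniformly) and ranks the remaining genes by
centrality loss. The single-sample disruption score is the mean absolute
z-deviation of a neighborhood's expression from a reference group's
mean/SD; samples are split into high/low subtypes by one-dimensional
2-means with deterministic initialization at the score minimum and
maximum (the two-way split is descriptive; no clustering method is claimed
beyond that).

## Module scores

The z-score method standardizes each module gene across samples (n-1
divisor) and averages over genes; inflammation, migration and pathway
activation scores are all instances with different gene lists. Genes with
zero variance are dropped and counted. The ssGSEA variant ranks a sample's
genes descending (ties broken by gene ID), weights in-set genes by
`(N + 1 - position)^alpha` with alpha = 0.25 so the top-expressed gene
carries the largest weight, and accumulates the gap between the weighted
in-set ECDF and the unweighted out-of-set ECDF over the whole list
(unnormalized enrichment statistic). Scores therefore depend only on each
sample's ranking and are invariant under strictly monotone transforms.

## Dose-response threshold

Cells are sorted by driver expression with ties broken by stable input
order — in single-cell data a large fraction of cells sits at zero, and
value-based quantile bins would collapse — and split into equal-count bins
(sizes differ by at most 1). The threshold fit grid-searches bin
boundaries b = 1..n_bins-2; for each, the model is a free constant on bins
1..b and a free straight line (in bin-center percentile units) on the rest,
fitted by least squares. This deliberately discontinuous 3-parameter form
guarantees the piecewise SSE never exceeds the straight-line SSE (the b = 1
model can reproduce any line exactly) — a nesting a continuous hinge would
violate. Ties go to the smallest percentile. A profile with all bin means
equal has no defined breakpoint and is flagged instead of fitted.

The Hill response `R(C) = R0 + tau (Emax - R0) C^h / (K^h + C^h)` carries a
transport-capacity factor tau in [0, 1]; tau = 0 pins the response at
baseline regardless of dose, which is the conceptual content of the
threshold pattern: below a minimum transport capacity, adding ligand does
not move the pathway. Defaults R0 = 0, Emax = 1, K = 1, h = 2; the
simulation is conceptual and is never fitted to data.

## Inference

*Differential expression.* log2 fold change is the group mean difference
on the log scale (identical across methods). Welch's t is the default;
the moderated variant shrinks per-gene pooled variances toward a prior
scale with prior df estimated by matching the mean and variance of the log
sample variances (digamma/trigamma inversion), testing on the augmented
df. BH correction runs across all genes.

*Rank-sum test.* Exact by full enumeration of label assignments (average
ranks, hence valid under ties) when the pooled size is at most 12,
otherwise the normal approximation with tie correction and no continuity
correction.

*Coherence.* Observed statistic is the signed mean pairwise Pearson r
among module genes (mean |r| available); the null draws B same-size sets
without replacement from all non-constant genes; p uses the add-one
formula, so min p = 1/(B+1).

*LOPO stability.* Drops each patient in turn and recomputes Cohen's d
(pooled SD) of the module z-score between outcomes; CV = sd/|mean| over
folds. Folds that empty a group are skipped with a warning.

*Path model.* All variables z-scored (binary outcome as 0/1 first);
a from OLS of inflammation on transport, (c', b) from OLS of outcome on
transport + inflammation; indirect effect a·b with a percentile bootstrap
CI over samples. The outcome is kept numeric (linear-probability
treatment), mirroring covariance-based path fitting; this means b is a
slope on the 0/1 scale, not a logistic coefficient.

## Repurposing

The disease signature takes the top n_up positive-t and top n_down
negative-t genes. Enrichment is the one-sided hypergeometric upper tail of
the overlap between each drug set (intersected with the background
universe — by default the analyzed matrix's genes, an explicit and
configurable choice) and each signature list; BH runs across all
set x direction tests. DOWN rows test the disease down-list: a drug set
enriched there opposes the disease profile. The reversal-subtraction
simulation shifts each reversal gene by `-w * s_g` (s_g = +-1, the gene's
disease direction) and re-scores the phenotype module with standardization
constants frozen from the unadjusted matrix, so the comparison isolates
the planted expression shift rather than partially cancelling it through
re-standardization. The weight w has no privileged value and the result is
labeled hypothesis-generating. A per-gene membership count across
significant sets is provided as a purely descriptive recurrence screen.

## Synthetic data: what is planted and why

**Bulk cohort.** 9 healed + 8 non-healed patients, 3-10 serial samples
each (~115 samples), 2000 genes, log-scale values with unit noise SD. The
transport module (40 genes) shares a per-sample latent factor f with
loading sqrt(rho), giving expected pairwise correlation rho per group
(0.5 healed / 0.8 non-healed by default — only the non-healed module
clears the 0.6 edge threshold). A per-patient, per-gene random intercept
(SD 0.1) models repeated measures without inflating cross-gene
correlations; it attenuates the expected module correlation by
1/(1 + 0.01), which the recovery tests account for.

The hub is the module gene with loading 1. This single choice produces the
planted topological asymmetry: in the non-healed network the hub sits
inside the module near-clique, while in the healed network its
hub-to-member correlations (sqrt(0.5) = 0.71) still exceed the threshold
although member-member pairs (0.5) do not — a star. Deleting a star's
center removes many open wedges and sharply perturbs global clustering, so
the hub's healed-network impact is strongly negative while every other
gene's is near zero, and DI = impact_nonhealed - impact_healed puts the
hub at rank 1 robustly. Fifteen spoke genes couple to the hub at r = 0.7
in both groups, enlarging its neighborhood. The rest of the transcriptome
is organized into 13-gene background modules at rho = 0.72 — real
transcriptomes are modular, and this stable triangle/triplet mass keeps
the global clustering coefficient well-conditioned so knockout impacts
reflect planted topology rather than sampling noise in a near-empty graph.

The mediation chain: inflammation latent I = beta_TI f + sigma eps with
beta_TI = -2.3, so the implied standardized transport→inflammation slope
is beta_TI/sqrt(beta_TI^2 + sigma^2) = -0.92. Patient-level healing is
drawn Bernoulli(logistic(alpha + beta_IH mean(I))) with alpha centering
the expected split on the requested group sizes; patients are accepted
until both quotas fill, keeping outcomes genuinely stochastic at fixed
cohort composition. beta_IH defaults to -0.3: outcome selection tilts the
transport factor between groups, and a stronger coupling would make the
hub differentially expressed through selection alone, destroying the
planted "topologically critical but DE-invisible" condition; the weak
coupling also matches the intended regime in which the
inflammation→outcome path is present but not strong. The hub additionally
carries a +0.1 log2 shift in the non-healed group — small against the
sampling noise of ~115 samples, hence non-significant in ~95% of cohorts.
Twenty inflammation-module genes load 0.6 on the standardized inflammation
latent (kept below the edge threshold after products so the inflammation
module does not fuse with the transport module in the graph).

An exactly calibrated null configuration for type-I-error checks sets
hub shift 0, beta_IH 0 and a balanced design (6 samples per patient): the
per-patient means are then iid normal and the two-sample t-test on them is
exactly uniform under the null. At the sample level the t-test is mildly
anticonservative under repeated measures (design effect ≈ 1.05) — a
property of clustered designs, not of the generator.

**Single-cell dataset.** 3000 cells x 1000 genes. The driver's latent
abundance has a point mass at zero (0.15) plus Gamma(2, 1); observed
counts are Poisson with rate 3 x latent times a shared per-cell depth
factor, so a genuine zero-detection stratum exists even without dropout.
Pathway modules (3 x 30 genes) stay at baseline log-rate below the planted
30th latent percentile and rise linearly above it (slope 0.5 per latent
unit, saturating at +1.5 — receptor signaling saturates, and an uncapped
response would let activated cells' library sizes swamp normalization).
The migration module (30 genes) is shifted +0.5 log-rate in
top-quartile-latent cells. Dropout zeroes entries independently at rate
0.1; higher rates migrate activated cells into the observed-zero stratum
and push the detected threshold upward. Housekeeping genes guarantee
positive cell totals. Detected thresholds land at the 30th-40th observed
percentile: Poisson noise and the zero stratum blur the latent boundary
upward by up to one decile, which the ±10-percentile recovery band
reflects.

**Drug library.** Random sets drawn uniformly from the background plus one
planted set sharing an exact number of genes with the signature's down
list — at overlap 30/100 against a 200-gene list in a 2000-gene universe
the planted set dominates 50 random sets by Fisher p essentially always.

### What the generator does not emulate

No sequencing-depth or GC biases, no batch effects, no cell types or
UMI chemistry, no time trend in the longitudinal design (weeks are drawn
uniformly; the repeated-measures structure is a random intercept only),
gene-gene correlation limited to block modules, and gene lists that stand
in for curated pathway memberships. Passing recovery tests therefore shows
the estimators are correct and calibrated under the stated model, not that
real cohorts satisfy that model.

## Numerical conventions

- Variance estimators use the n-1 divisor throughout; "variability" for
  gene selection is plain variance of stored values, with lexicographic
  gene-ID tie-break.
- Correlation-threshold comparisons are strict (> 0.6).
- All orderings (DI, enrichment, TF correlation, signatures) break ties by
  gene ID for cross-platform determinism.
- log2 transformation of abundance tables uses offset +1.
- Pipeline stage seeds derive from the master seed via
  `numpy.random.SeedSequence` spawning; every stochastic stage is seeded
  and the report is bit-reproducible.
- Reported floats in `report.json` are rounded to 10 decimals so report
  hashes compare stably across runs.

## Problem sizes used in validation

Recovery and calibration checks run at the cohort scale the package
targets (~115 bulk samples, 2000 genes, 3000 cells) for 20 seeds, with
calibration loops (200 seeds) on reduced gene counts since only planted
rows are consumed; permutation tests use B = 999 in the analysis scripts
and smaller B in calibration loops where only the p-value's null behavior
matters.

## Known limitations

- Cohesion mixes a density term that scales like 1/n^2 with a clustering
  ratio that does not; on very sparse graphs the clustering term dominates
  and single-edge fluctuations move impacts more than degree differences.
  The DI contrast between two networks removes most of this sensitivity,
  but impact magnitudes should not be compared across networks of very
  different density.
- The moderated-t prior estimation assumes a common variance prior across
  genes; strongly mean-dependent variance would call for a trend-corrected
  estimator.
- The linear-probability path model estimates standardized associations,
  not causal effects; the mediation interpretation rests on the planted
  generative order in synthetic data and is hypothesis-generating on real
  data.
- The hockey-stick fit reports the SSE-optimal boundary on a fixed decile
  grid; thresholds between boundaries are rounded to the nearest feasible
  boundary.
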