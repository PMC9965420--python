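# Methods

## The model shared by all three views

Every stage assumes the same generative picture: a cohort of n bulk
expression profiles in which sample i is, up to noise, a convex mixture

    x_i = Σ_t w_it · a_t ,   w_i on the (k−1)-simplex,

of k extreme expression programs a_1..a_k ("archetypes"). The three stages
estimate this structure at different levels: the simplex fit finds the
a_t as vertices in latent space, the topic model estimates both the gene
distributions of the components (factors F) and the mixture weights
(loadings L) probabilistically, and deconvolution resolves the components
into individual reference cell states. Agreement among the three is itself
a checkable prediction and is quantified by the consistency report.

## Preprocessing

* **Probe collapse.** One row per gene, keeping the probe with maximal mean
  across all samples; the retained row is copied verbatim, never averaged.
  Ties break toward the lexicographically smallest probe identifier —
  the rule is arbitrary but deterministic and auditable.
* **Standardization.** `log2(x+1)` (offset +1 so zero maps to zero),
  per-row z-scores (n−1 denominator; constant rows become zero with a
  warning), or none. Log transformation is the default for intensity-like
  real data; the pipeline defaults to *no* transform for synthetic
  convex-mixture cohorts, whose geometry is linear by construction and
  would be curved by a log.
* **Outlier flagging.** Distance to the cohort center in variance-scaled
  coordinates of the first `n_pcs` PCs (default 3), converted to a robust
  z-score via median/MAD; samples above `z_cut` (default 4) are reported.
  Cohort outlier removal is ultimately a judgment call, so the rule is
  explicit, configurable, and returns a list rather than silently dropping
  samples.

## Archetype inference

PCA uses full-SVD with centered features; component signs are fixed so the
largest-magnitude gene loading is positive. The enclosing simplex requires
k = d+1 (triangle in the PC1–PC2 plane for k = 3).

The fit minimizes, over vertex positions V,

    volume(V) + λ · Σ_i Σ_t max(0, −b_it(V)) ,

where b_i are the barycentric coordinates of sample i and λ =
`penalty_weight` × (volume of the initial hull-based simplex); the default
`penalty_weight` = 10 makes leaving a point outside expensive relative to
any volume saved, while still tolerating stray noisy points (soft
containment in the spirit of SISAL's relaxation). Numerics:

* Data are canonicalized first — centered, scaled to unit RMS radius, and
  rotated onto their own principal axes with a rotation-invariant sign
  convention — so the fit is equivariant under rotation and scaling of the
  embedding by construction.
* Initialization is the max-volume simplex over convex-hull extreme points
  (exhaustive for ≤ 14 hull points, greedy otherwise), inflated by 15%.
* The soft objective is minimized by Nelder–Mead (a small number of
  seeded, jittered restarts), then sharpened by a smooth constrained solve:
  each point's current containment deficit is frozen as allowed slack and
  volume is minimized subject to `barycentric ≥ −slack` with SLSQP. The
  polish is kept only if it does not worsen the soft objective. This
  resolves the kink-point optimum to ~1e−9 where Nelder–Mead alone stalls
  at ~1e−2.
* Vertices are reported in angular order around their centroid until
  marker scoring assigns names (then alphabetical by label).

Back-projection maps a vertex v to gene space as `center + v·loadingsᵀ`,
flooring small negative values at zero (count logged). Archetype markers
are genes with `log2((p_t+ε)/(p_s+ε)) > 2` against *both* other archetypes
(ε = 1 pseudocount). Marker-set labeling uses the upper-tail hypergeometric
probability of the overlap between each archetype's marker list and each
library set over the declared gene universe; ties break toward larger
overlap, then set name; empty lists are labeled "unassigned".

## Topic model

The count matrix X (genes × samples) is modeled as X ~ Poisson(WH). For
microarray-style continuous input, each sample is rescaled to a fixed total
(default 10⁴) and rounded, since the likelihood is defined on counts;
integer input is used as-is. Optimization is the classic two-phase
schedule: multiplicative EM updates (monotone for the Poisson/KL
objective), then cyclic coordinate descent — for each topic, a Newton step
on the per-row objective taken simultaneously for all genes (rows are
independent given the other factor), with per-row halving until the
objective has not decreased. The likelihood trace is therefore
non-decreasing by construction; defaults are 100 EM + 100 CD iterations,
3 random restarts (uniform positive initialization from the seed), best
final likelihood kept.

The factorization is rescaled to the simplex parametrization: F = W
column-normalized (p(gene|topic)), L row-normalized from H and the column
scales (topic proportions per sample). Posteriors use Bayes' rule with a
uniform prior by default; genes with zero likelihood under all topics
return the prior with a warning. Gene lists take posterior > 0.5, which
guarantees at most one topic per gene. Pairwise topic log2 fold changes use
a negligible pseudocount (1e−10) on F.

Identifiability note: topic order is arbitrary; all recovery metrics and
reports align components first (assignment problem maximizing summed
Pearson correlation).

## Deconvolution (cell population mapping)

Two steps. *Deconvolution*: N runs, each drawing `modelSize` = 50 reference
cells uniformly without replacement and fitting linear ν-SVR (ν = 0.5,
C = 1) with genes as observations; a cell's abundance is the mean of its
coefficients over the runs in which it was drawn. N starts at
`ceil(minSelection·C/modelSize)` and deficit-aware top-up runs (deficient
cells included first) make "every cell drawn ≥ minSelection = 5 times" a
hard guarantee. *Extrapolation*: each cell's abundance is averaged over its
`neighborhoodSize` = 10 nearest neighbors (itself included, Euclidean in
the provided 2D embedding). Type proportions clip smoothed abundances at
zero, sum per type, and normalize each sample to 1; an all-zero row falls
back to uniform with a warning.

Numerical choices:

* Both matrices are standardized by the *global* mean and SD of the
  reference after gene intersection. Per-gene z-scoring was rejected: it
  recenters every gene so that cell types contributing less than the
  cohort-average signal receive systematically negative coefficients,
  which the clip-then-normalize step then discards — on noiseless
  orthogonal-support benchmarks this inflates type-share RMSE from ~0.01
  to ~0.19. Global scaling preserves the per-gene geometry while keeping
  the regression well-scaled; it assumes bulk and reference are on a
  comparable normalization (e.g. equal totals), which the caller should
  ensure.
* libsvm's default stopping tolerance makes each fit needlessly slow at
  this precision; the SVR runs with tol = 1e−2 and max_iter = 5000
  (coefficients correlate > 0.999 with fully converged fits), both exposed
  as parameters.
* Negative coefficients are retained through smoothing and clipped only at
  type quantification, so local negative evidence can cancel positive
  noise before aggregation.

## Synthetic-data generator

The generator *is* the study condition for validation, not a tunable
harness:

* Archetype profiles are sparse gamma variates (shape 0.4, 30% zeroed)
  with per-archetype exclusive marker blocks (default 25 genes, gamma
  shape 5 scale 2, +5 offset), each profile rescaled to a fixed total
  (default 10⁴) so every convex mixture has the same expected depth.
  Mixture weights are Dirichlet (default α = (1,…,1), the uniform
  distribution over the simplex).
* Noise is Poisson on expected counts by default; a mean-preserving
  lognormal multiplicative option (σ = 0.3) covers intensity-like data.
  Neither claims to be the noise law of any particular platform; they are
  the two canonical families for counts and intensities.
* The single-cell reference places each type as a Gaussian cluster
  (σ = 1 around centers on a radius-10 circle) in the 2D embedding —
  deconvolution's smoothing only needs same-type cells to be mutual
  neighbors, so no manifold-learning step is simulated. Cell profiles
  jitter around type means with gamma noise (CV 0.3). `orthogonal_support`
  gives types disjoint expressed gene blocks, making the noiseless
  deconvolution problem exactly solvable and the benchmark interpretable.
* `make_linked_reference` ties the reference types to a mixture cohort's
  archetypes and reuses its weights as the bulk composition, giving one
  planted truth that drives all three views for end-to-end consistency
  checks.

What passing on these cohorts does *not* show: robustness to batch
effects, probe-level artifacts, platform-specific noise, partial overlap
between reference and bulk cell populations, or cross-species gene
mapping. Real-data behavior on those axes is untested here by design.

## Problem sizes and defaults in the validation suite

Recovery checks run at 500 samples × 500 genes (archetypes), 200 × 500
(topics, 100 EM + 100 CD), and 300 reference cells / 20 bulk samples
(deconvolution, modelSize 50 / minSelection 5 / neighborhoodSize 10);
the end-to-end consistency cohort is 120 × 300 with an 80-cells-per-type
reference. These sizes make every recovery criterion sharp (errors well
inside their tolerances) while keeping the full suite a desk-scale run.

## Known limitations

* Simplex order selection (choosing k) is out of scope; k is a modeling
  choice, constrained to k = d+1.
* The topic model's count conversion for continuous intensities (rescale
  to 10⁴ and round) is a pragmatic stand-in; there is no canonical mapping
  from intensities to counts.
* The CPM interpretation averages a cell's coefficients over the runs in
  which it was drawn (not over all runs); with the sampling guarantee this
  is an unbiased per-cell summary but differs from averaging zeros in.
* Poisson-NMF likelihoods are multi-modal; on weakly structured data
  different inits (or permuted inputs) can reach different local optima.
  Restarts mitigate but do not eliminate this.
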