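# Methods

## Model and procedure

The package treats a molecular profiling matrix (N features × D samples)
as D points in N-dimensional feature space. The analysis pipeline is:

1. **Filtering.** Feature rows with non-finite entries are dropped (never
   imputed — imputation would inject modeling assumptions the QC question
   does not need); optionally zero-variance rows too. Named features (e.g.,
   sex-chromosome probes) can be excluded wholesale. Every drop is logged
   with counts, because "why did this sample move?" detective work depends
   on knowing exactly what went in.
2. **PCA.** The matrix is centered feature-wise and decomposed by thin SVD
   of the centered N×D matrix; sample scores are `VΣ`. This is standard
   sample-mode PCA: samples are the observations, and the SVD route avoids
   forming either covariance matrix, which matters when N ≫ D. Eigenvalues
   use the 1/(D−1) denominator, so eigenvalue *l* equals the variance of
   score column *l*; explained-variance fractions are
   denominator-independent. Each component is oriented so its
   largest-magnitude feature loading is positive (ties → lowest feature
   index), making scores and plots bit-reproducible across platforms. The
   covariance-eigendecomposition route survives only as a test oracle.
3. **Centroids, rays, trends.** A group's centroid is the arithmetic mean
   of its members' score rows; the size-weighted mean of all centroids is
   the origin by construction. Plot geometry lives in a declarative,
   JSON-serializable `PlotSpec` (points, centroids, rays, arrows), so all
   geometric contracts are tested on coordinates, not pixels; rendering is
   a thin matplotlib pass. Colors are a pure function of the sorted level
   list (fixed 20-color cycle; overflow reuses colors with new marker
   shapes, logged).
4. **DSC.** See README for the definition. Both dispersions are computed
   as streaming sums over coordinates (`dsc_fast`); the explicit
   scatter-matrix construction (`dsc_naive`) is retained as an independent
   oracle and the equivalence of the two — an algebraic identity — is
   asserted to 1e-10 relative in the tests. Reports always pair an
   "overall" DSC (full retained feature space) with a "pca-L" DSC (the L
   plotted score columns, unweighted — scores already carry variance
   scale): the overall value summarizes the whole data, the PC-space value
   matches what the plot shows.
5. **Permutation test.** Labels are shuffled uniformly (group sizes
   preserved by construction) `n_perm` times, sampling the assignment
   space with replacement; `p = #{null ≥ observed}/n_perm`, ties counting
   toward the null, with an optional (count+1)/(n_perm+1) smoothing flag
   (off by default). Default `n_perm` = 2000, giving p-value resolution
   5e-4. Both spaces of a report share one generator stream seeded once.

## Conventions and degenerate inputs

- **D_b/D_w square-root convention.** The dispersions are defined as
  square roots of the scatter-matrix traces, so that `D_b² + D_w²` equals
  the total mean squared deviation about the global mean (law of total
  variance) — asserted on every tested instance. The naive oracle applies
  the same convention, keeping the equivalence test meaningful.
- **Group priors** are always `π_j = s_j/N`; no other prior is supported.
- **D_w = 0 with D_b > 0** (each group constant, groups apart) raises a
  `ZeroWithinDispersionError` carrying D_b — the ratio is unbounded and a
  number would be misleading. **D_w = D_b = 0** (all data identical)
  yields DSC = 0 with a warning. Inside the permutation loop these cases
  become +inf and 0 respectively: a permuted labelling is never silently
  dropped, and +inf conservatively counts toward the null tail.
- **Singleton groups** are allowed (they add 0 to D_w) with a logged
  warning: single outlying samples can inflate the DSC while the p-value
  stays non-significant.
- **Thresholds 0.3/0.6** classify boundary values as "moderate" (closed
  interval) — the rule of thumb is stated as an open "between".
- **Sample/annotation mismatch** is resolved by intersection with a loud
  warning, keeping multi-variable workflows usable; scores and labels are
  always index-aligned, never silently reordered.

## Synthetic data: what it emulates, what it does not

`SyntheticSpec` draws spherical Gaussian groups in feature space with a
controllable mean shift δ between consecutive group centroids (along all
features, the first axis, or a random unit direction), temporal drift for
trend scenarios, and a hidden binary variable ("sex") adding ±effect to a
tagged feature subset for dichotomy scenarios. The closed-form population
DSC of such a scenario is
`sqrt(Σ_j π_j ‖μ_j − M‖²) / (σ √d)`, which the empirical statistic
approaches for large samples.

Defaults mirror the intended QC regimes: 3 groups × 20 samples × 200
features, σ = 1, δ = 1 (a modest batch effect); dichotomy scenarios use
effect/σ = 8 on 10% of features with ~40 samples, a deliberately blatant
dichotomy of the kind sex-chromosome probes produce in methylation data.
Simulation-based tests stay at ≤ 60 samples and ≤ 500 features so the
whole suite runs in seconds.

What the generator does **not** emulate: platform-specific value
distributions (methylation β-values are bounded, expression log-ratios are
heavy-tailed), feature–feature correlation, scale (variance) batch
effects, and missingness patterns. Passing tests therefore demonstrate
correctness of the statistics and geometry under the Gaussian location
model, not robustness to real-data pathologies; the DSC's known outlier
sensitivity is exercised by the singleton-group warning path rather than
by a heavy-tailed noise family.

`mean_center_by_batch` is a location-only correction (subtract each
batch's per-feature mean, restore the global mean). It removes a pure
mean-shift batch effect *exactly*, which is precisely what the
before/after QC workflow needs to demonstrate; it is not a
shrinkage/empirical-Bayes method, does not touch scale effects, and will
partially absorb any biological variable confounded with batch.

## Numerical and design choices

- **Parameter-recovery check** (empirical vs population DSC at
  n = 500/group): the empirical between-group dispersion is inflated by
  estimation noise, `E[D̂_b²] ≈ D_b² + dσ²(k−1)/N`. With the check's
  smallest effect (δ/σ = 0.5, D_b² = δ²/4) this inflation is
  `0.064·d/4` relative, so the scenario uses d = 4 features, keeping the
  predicted bias (~3%) inside the 5% agreement band; results are averaged
  over 8 independent draws to suppress Monte-Carlo noise.
- **Null calibration** uses K=3 × 10 samples × 20 dims, 200 permutations,
  200 replicates — the rejection rate at α = 0.05 has standard error
  ~0.016, hence the [0.02, 0.09] acceptance band.
- The permutation p-value is slightly conservative (sub-uniform) because
  duplicate permutations are allowed and ties count toward the null.
- TSV/CSV round-trips write `%.17g`, preserving doubles exactly.
- SVG output pins the hash salt and omits the date so identical specs
  render byte-identically.

## Known limitations

- No analytic null distribution for the DSC; inference is purely
  permutation-based, so p-value resolution is 1/n_perm.
- DSC values across many annotation variables are reported raw; no
  multiple-testing correction is applied (documented, by design).
- 2-D plots only; component pairs other than (1,2) are selectable but
  3-D/animated views are out of scope.
- The DSC compares *location* separation to dispersion; batch effects that
  differ only in variance or correlation structure can have DSC ≈ 0 while
  still being real.
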