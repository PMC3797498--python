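# Methods

This note documents the statistical models implemented in `ecoassembly`, the
choices made where conventions diverge, and what the synthetic-data tests do
and do not demonstrate about real surveys.

## Null model and turnover deviation

The regional species pool is the set of species observed across all plots
with their total abundances; plot totals N_j are the observed per-plot
individual counts. Two randomization schemes reassemble plots from the pool:

* `without_replacement` (default): a uniform random allocation of the pooled
  individuals to plots with fixed margins — every plot keeps N_j exactly and
  every species keeps its exact pool total. Implemented as a shuffle of the
  expanded individual vector split at the plot totals.
* `with_replacement`: each plot draws N_j individuals from a multinomial with
  the pool's relative abundances; species totals are preserved in expectation
  only.

Exact margin preservation is the default because it matches individual-based
randomization as usually practiced; the multinomial variant exists because it
is the exact generative dual of the neutral limit of the community simulator
(see below), which makes calibration arguments clean.

For each plot pair the turnover deviation is the standardized effect size
(observed Bray–Curtis − null mean) / null SD, with the sample (n−1) SD over
`n_iter` iterations (default 1000, the conventional choice). The deviation is
kept as a full pair × pair matrix — not only a scalar mean — because the
downstream Mantel tests correlate it against distance matrices. Pairs whose
null SD is below 1e−12 (e.g. a single-species pool under exact margins) are
set to NaN, counted, and excluded from tests rather than producing
infinities. Iteration i's randomized matrix is a pure function of (seed, i)
via independent child seed sequences, so runs are reproducible and
parallelizable.

`test_mean_deviation` is a two-sided one-sample Student's t-test of the
condensed deviation values against zero, df = n_pairs − 1, as is standard in
this literature.

**Known limitation — the t-test's effective sample size.** The n(n−1)/2
pairwise deviations are not independent: pairs sharing a plot are positively
correlated. On neutral data (25 plots) the empirical SD of the mean deviation
is ≈0.19 while the nominal standard error is ≈0.06, so the test rejects a
true null far more often than its nominal 5% (we measure ≈50%). The statistic
is implemented as conventionally defined and its calibration is reported
honestly by `scripts/acceptance.py` (`neutral_t_test_rejection_rate`); for
real inference the Mantel tests and the partition's permutation tests — which
are properly calibrated (measured type-I ≈ 0.05) — carry the evidential
weight. The *mean* deviation itself is unbiased: it centers on zero under
neutral assembly.

## Distances

Community dissimilarity is abundance-based Bray–Curtis. Environmental
distance is Euclidean on the z-scored retained variables (standardization
chosen because the variables' units are incommensurable; a flag restores raw
values). Geographic distance is Euclidean on planar meter coordinates;
lon/lat input is projected by an equirectangular projection at the mean
latitude, whose error is negligible at tens-of-kilometers extents.

## Mantel family

`mantel_test` correlates condensed distance vectors (Pearson) and permutes
the response matrix's rows and columns simultaneously. The default tail is
one-sided (greater), since the working hypotheses are directional (turnover
rises with distance); two-sided is a flag. p-values use the add-one estimator
(1 + #{r_perm ≥ r_obs})/(n_perm + 1), so p ≥ 1/(n_perm+1) and is never zero.
`partial_mantel` correlates the residuals of A and B on the control matrix C
and permutes the raw A matrix before residualization (Legendre's method; the
residual-permutation alternative is not implemented). If a residual vector
vanishes identically (e.g. controlling A for itself) its correlation is
defined as 0. `mrm` is OLS on condensed vectors with permutational
coefficient tests (two-sided on t) and a one-sided overall-R² test.
Default permutation count is 999 throughout.

## PCNM spatial eigenfunctions

Truncation distance defaults to the longest edge of the Euclidean minimum
spanning tree — the smallest threshold keeping the neighbor graph connected.
Distances above it are replaced by 4× the threshold; the matrix −D²/2 is
Gower double-centered and eigendecomposed; eigenvectors with eigenvalue
> 1e−9 × the largest are retained (positive spatial autocorrelation only),
named PCNM1, PCNM2, … in descending eigenvalue order. Signs are fixed by
making each column's largest-magnitude loading positive, so results are
identical across linear-algebra backends. The construction was verified
against the reference R implementation (`vegan::pcnm`) on a 50-point
transect: identical threshold, retained count (33) and eigenvalues. Note the
low-order eigenfunctions of this classical construction are broad but
edge-modulated waves — PCNM1 correlates with a half-period cosine at
|r| ≈ 0.87, not ≈ 1.

## RDA, forward selection, variation partitioning

RDA is multivariate least squares of the column-centered (Hellinger)
community matrix on centered predictors; R² = SS(fitted)/SS(total), canonical
eigenvalues from the SVD of the fitted matrix. Partial RDA residualizes both
response and predictors on the conditioning block and reports the semipartial
R² (share of *total* response SS). Predictor columns lying entirely within
the span of the conditioning block explain nothing and are dropped; rank
deficiency among the remaining columns is an error that names the dependent
columns.

Permutation F-tests use F = (SS_explained/m)/(SS_residual/(n−m−q−1)). Without
conditioning variables the response rows are permuted freely; with
conditioning, the residuals of the response on W are permuted and
re-residualized (reduced-model permutation), which controls type I error in
partial tests. Measured type-I error is ≈0.05 with uniform p-values.

Forward selection is greedy: each step adds the candidate with the largest
added explained SS given the selected set, accepts it only if its conditioned
permutation F-test has p ≤ α (default 0.05, 999 permutations), and stops
otherwise. Ties break by candidate order; the procedure is deterministic
given the seed. The cumulative-adjusted-R² double-stopping rule is available
(`double_stop=True`) but off by default. A `max_select` cap exists because
the adjusted-R² partition requires n > m_E + m_S + 1; the pipeline caps each
block at (n_plots − 2)//2. Selecting with α = 0.05 over k candidates inflates
the family-wise error; this is conventional and left uncorrected.

Adjusted R² uses Ezekiel's formula 1 − (1−R²)(n−1)/(n−m−1) for every block,
including PCNM blocks, with m = the rank of the block's column space (so
degenerate unions are handled rather than erroring). With a = adjR²(E∪S),
b = adjR²(E), c = adjR²(S), the partition is [E|S] = a−c, [S|E] = a−b,
[E∩S] = b+c−a, residual = 1−a; the four sum to 1 exactly, and slightly
negative fractions are reported as computed (clamping would break the
identity). [E∩S] is not the R² of any model and carries no test; the
conditional fractions are tested by reduced-model partial-RDA permutation.
The partition was verified against `vegan::varpart` (agreement to 1e−7 on a
fixed dataset).

## Synthetic surveys

The generator emulates a hierarchical forest survey: `n_sites` (5) site
centers along a transect of `extent_m` (30 km), `plots_per_site` (5) plots
scattered within `site_spread_m` (300 m), giving 25 plots. Each of the 11
environmental variables is a weighted linear transect gradient plus a
spatially autocorrelated Gaussian field (exponential covariance, range
`env_autocorr_range_m` = 10 km, generated by covariance factorization at the
plot locations only) plus white noise (SD 0.3); one variable is a circular
aspect in degrees, which the pipeline splits into sin/cos. These ranges give
environment–geography Mantel correlations comparable to real transect
surveys, which is the feature that matters here (it produces a large shared
fraction [E∩S], as observed in field studies).

Species i gets a lognormal base abundance, a niche optimum near the
(standardized) environment of a random plot, and a geographic aggregation
center. Expected relative abundance at plot j is

base_i · exp(−ω·‖z_j − μ_i‖²/p) · exp(−δ·d(j, c_i)/extent),

a Gaussian niche response (ω per squared z-unit, averaged over p axes) and an
exponential dispersal kernel (δ per transect extent — δ = 8 means abundance
falls by e⁻⁸ across the transect). Plot totals are Poisson (mean 200) and
individuals multinomial, so at ω = δ = 0 assembly *is* the with-replacement
null model. The three-layer bundle shares one landscape and uses
(ω, δ) = (4, 1) herb, (3, 2) shrub, (0.3, 8) canopy with 80/102/34 species —
niche-dominated understory, dispersal-dominated canopy.

What the generator does not emulate: demographic dynamics (birth–death,
drift, speciation), interspecific interactions, temporal turnover, sampling
error in environmental measurements, and observational artifacts (detection
failure, taxonomic lumping). Passing recovery tests therefore demonstrates
that the pipeline identifies the processes *it models* under realistic sample
sizes — not that those processes are separable in any particular field
system, where unmeasured spatially structured environment remains the classic
confounder of the pure-spatial fraction.

## Problem sizes and numerics

Simulation-based checks use: 200 neutral datasets × 1000 null iterations for
calibration; 500 replicates × 199 permutations for type-I error; 100
replicates per condition (forward selection at 99 permutations) for process
recovery. These sizes give binomial standard errors of ~1–2 percentage points
on the reported rates. Degenerate inputs are handled explicitly: all-zero
plot rows are rejected at validation, zero-variance condensed vectors and
constant environmental columns raise errors naming the offender, null-SD
zeros become excluded pairs, and p-values are never exactly zero by the
add-one convention. All stochastic stages consume seeds fanned out from one
master seed through named seed sequences, so every report is bit-reproducible.
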