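# Methods

## Model

The two-way model is

    Y = β0 + β1·X1 + β2·X2 + β3·X1^M · X2^N + ε,      ε ~ N(0, σ²) i.i.d.

with continuous, non-negative predictors (in practice 0–1 standardized)
and real exponents M, N.  At M = N = 1 it reduces to the classical
product-interaction regression; the exponents deform the interaction
surface while the model stays linear in its four coefficients, which are
estimated by ordinary least squares at every candidate exponent pair.
The "plus" variant appends quadratic main effects β4·X1² + β5·X2²; the
three-way variant uses β4·X1^M·X2^N·X3^K with three main effects.

Assumptions worth stating plainly: a *single* interaction term; Gaussian
homoscedastic errors (all t-tests and AIC values rely on this); exponents
shared across the whole sample (no regimes); and predictors on a
non-negative scale — fractional powers of negative numbers are undefined,
so negative columns are rejected with advice to transform.

## The exponent grids

**Initial grid (stage 1).** 55 values per exponent spanning [−52.5, 52.5],
symmetric about 0, containing 0 and ±1 exactly, with spacing
non-decreasing in |value| so that the physically common region near zero
is sampled densely.  Construction (positive half, mirrored for the
negative half, plus 0): 13 inner values (i/13)², i = 1…13, ending exactly
at 1; then 14 outer values 1 + 51.5·(j/14)^p, j = 1…14, with p chosen in
closed form so the outermost spacing is exactly 7.  That last choice is
deliberate: the stage-2 neighbourhood of an edge winner extends outward by
half the edge spacing, so the reachable range is exactly ±56.  The grid is
deterministic and is embedded in every result file, so outputs are
self-describing.

**Tuning grid (stage 2).** Around the stage-1 winner, 10 evenly spaced
values filling the winner's half-spacing cell (midpoint with the left
neighbour to midpoint with the right neighbour).  Cells of adjacent grid
points tile the line, and the 10 points are placed half-open —
right-closed for positive centers, left-closed for negative, symmetric
open for 0 — so the union over all 55 centers is exactly 550 distinct
values per exponent and the two extreme cells reach ±56.  The tuning-grid
spacing ("tuned step") is the search's native resolution; recovery claims
are made at that resolution.

**Selection.** Highest R² among all valid candidates of both stages.
Within a stage all candidate models have the same term count, so R²,
adjusted R² and AIC order candidates identically; across the two stages
the winner is simply the best candidate seen.  Exact R² ties are broken
toward the exponent pair closest to all-ones (parsimony toward the
classical model), then lexicographically.  Candidates whose interaction
column is non-finite (zero base under a negative exponent, overflow) or
numerically collinear with the base columns are skipped with a reason
code in the candidate table — with 0–1 standardized data a zero minimum
makes every negative exponent invalid, so this is routine, not
exceptional.  If the fast scorer accepts a candidate that the exact
refit's rank check rejects, that candidate is downgraded and the next
best is refit instead.

**Three-way search.** 55³ stage-1 fits are disproportionate, so stage 1
scans every other initial value (28 per exponent, keeping ±1 so the
classical product model remains a candidate; 28³ fits), and stage 2 tunes
all three exponents with 10 values each (1000 models) in the *coarse*
grid's half-spacing cells — the tuning neighbourhood must come from the
grid stage 1 actually scanned, or truths in skipped cells would be
unreachable.  `coarsen=False` restores the full grid.

## Numerics

Stage scoring uses the projection identity: with the base columns
(intercept, main effects, quadratics if present) reduced to an
orthonormal basis Q once per dataset, the RSS of base-plus-candidate is
RSS(base) − (r_z·r_y)²/(r_z·r_z), where r_z, r_y are residuals after
projecting out Q.  Candidate columns are normalized to unit length first
(the R² gain is scale-invariant), which keeps extreme exponents from
overflowing; columns whose residual norm is below 1e-8 of their own norm
are declared collinear — below that the gain ratio is numerically
unstable, and under a null interaction such candidates would win on
amplified noise alone.  The winning model is then refit exactly through
the SVD-based OLS engine (rank tolerance 1e-10 on relative singular
values), which supplies coefficients, SEs from the unbiased variance
estimate, t-test p-values on n − k degrees of freedom, and the Type I
sequential sum of squares obtained from nested refits in declared term
order.  The vectorized scan is checked against an independent exhaustive
double loop in the test suite.

## AIC conventions

AIC is computed from the Gaussian profile likelihood,
`n·log(2π·rss/n) + n + 2·(p+1)`, the convention of mainstream statistical
software (the +1 counts σ²).  Two variants are reported: `aic_naive`
counts only the linear coefficients; `aic_adjusted` additionally counts
the searched exponents (two, or three for the three-way model) — an
exponent chosen from 550 candidates consumes degrees of freedom like any
estimated parameter, and comparing a searched model to an unsearched one
on `aic_naive` alone flatters the search.  The comparison report likewise
carries both `residual_df` (n − k, used for the t-tests) and
`residual_df_effective` (n − k − searched exponents).

## Sequential decomposition and the interaction share

Type I sums of squares are computed in the declared order: main effects,
then (for the plus variant) quadratics, then the interaction.  Placing
the quadratics *before* the interaction makes the reported interaction
share conditional on main-effect curvature — under a purely quadratic
truth the share correctly stays near zero rather than absorbing the
curvature.  The interaction share is the interaction's sequential SS over
the total SS; the decomposition plus the residual SS reproduces the total
SS identically on every fit (asserted in tests).

## Synthetic data and what it does (not) show

`SyntheticSpec` generates data from the model's own generative structure:
predictors i.i.d. uniform(lo, hi) on (0, 1] by default, or lognormal
rescaled to (lo, hi) to mimic right-skewed field covariates; Gaussian
noise; every draw a pure function of the integer seed (replicate seeds
derive from one seeded generator, never the clock).  Defaults are the
package's reference conditions: n = 500, β = (0.25, 0.1, 0.9, 9.8),
(M, N) = (4.9, 2.6), noise SD 0.05, predictors uniform(0.05, 1).

Because the generator matches the model, recovery experiments validate
the *search* (does the two-stage argmax find the generating exponents at
its grid resolution?) and the *null behaviour* (with β3 = 0 the mean R²
gain over the regular model stays well under 0.02 at n = 1000), not
robustness to model misspecification: real data have correlated,
non-uniform predictors, heteroscedastic and autocorrelated errors, and
interactions that are not exactly of power form.  Passing tests therefore
say the machinery is correct, not that the power form is right for any
particular dataset.

One identifiability caveat the experiments expose: the R² surface has a
flat ridge trading M against N (larger M with larger N fits similar
surfaces), so with noisy data the selected pair can land one grid cell
along the ridge away from the truth even when the fit is essentially
perfect.  Recovery is accordingly judged *within one tuned-grid step*,
and at the reference conditions with true (M, N) = (3, 2) both exponents
land within one step in every one of 20 replicates; at the steeper
(4.9, 2.6) truth individual replicates occasionally settle on the
adjacent ridge cell.  Noiseless data whose true exponents lie on the
stage-1 grid are always recovered exactly (R² = 1 at the truth, which the
argmax must select).

## Problem sizes

Validation uses n = 100–1000 rows and 20 replicates per experiment; a
full two-stage two-way search (3125 OLS scores + exact refits) takes
about 0.1–0.3 s at n = 500 on one CPU, the coarsened three-way search
(22,952 candidates) under half a second at n = 800.  These sizes give
stable recovery fractions while keeping the whole suite fast.

## Known limitations

* Continuous predictors only; categorical interactions are out of scope.
* One interaction term per model (one two-way or one three-way).
* No confidence intervals on (M, N) — the search is a discrete argmax,
  and the ridge geometry would make Wald-style intervals misleading.
* No continuous (gradient-based) refinement of the exponents beyond the
  550-value reachable set.
* Exponent estimates are only meaningful at the tuned-step resolution,
  which is coarser far from zero.
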