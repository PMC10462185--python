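# Methods

## Model and test

Consider a two-arm longitudinal animal study with tumor volumes Y_{g,ij}
for animal *i* of group g ∈ {0, 1} at time points j = 1, …, m.  At each
time point j > 1 the homologous test compares the groups' conditional mean
volumes given each group's *observed* mean at the preceding time point:

    H0: E(Y_{0,j} | Y_{0,j−1} = ȳ_{0,j−1}) = E(Y_{1,j} | Y_{1,j−1} = ȳ_{1,j−1}).

Because the group covariate means converge to the population means, this
null is asymptotically equivalent to the marginal mean-equality null; at
finite n it differs by an O_p(1/√n) neighborhood term, and that subtle
difference is the price of the efficiency gain.

Assuming a linear conditional-mean relationship between adjacent time
points in each group, the two groups combine into one interaction
regression at time j,

    Y = β0 + β1 x + β2 y_prev + β3 x·y_prev + ε,   ε iid N(0, σ_j²),

with x the treatment indicator.  The joint fit decouples exactly into the
two within-group simple regressions (group 0: intercept β0, slope β2;
group 1: β0+β1, β2+β3).  The test statistic is the contrast

    z = (0, 1, ȳ_{1,prev} − ȳ_{0,prev}, ȳ_{1,prev}),    D̂ = z β̂,

with variance estimate s²_D̂ = MSE · z (X′X)⁻¹ z′, MSE = SSE/(n−4), and
D̂/s_D̂ ~ t_{n−4} under H0.

Three exact algebraic identities anchor the implementation and are enforced
as property tests over arbitrary non-degenerate data:

1. **Mean-difference identity.** D̂ equals ȳ_{1,j} − ȳ_{0,j}, the raw
   difference of group sample means — the conditional estimate at each
   group's own covariate mean is that group's sample mean, because a
   least-squares line passes through (x̄, ȳ).
2. **Leverage identity.** z (X′X)⁻¹ z′ = 1/n0 + 1/n1: the contrast sits at
   each group's covariate centroid, where that group's leverage is 1/n_g.
   Hence s²_D̂ = MSE·(1/n0 + 1/n1), and the gain over the t-test comes
   entirely from MSE estimating the *residual* variance σ² ≈ (1−ρ²)·Var(Y)
   instead of the marginal variance.
3. **Decoupling.** The joint interaction fit reproduces the per-group
   simple-regression coefficients exactly.

The per-group conditional path (within-group regression of y_curr on
y_prev; estimate = group mean; SE = √(MSE_g/n_g) with MSE_g on n_g − 2
denominator) is reported descriptively in scan output alongside the
conventional s_g/√n_g.  The regression path (pooled MSE, df n − 4) is the
canonical p-value source, because only it carries an exact finite-sample
null distribution; the per-group variances Var̂ = MSE_g/n_g are symmetric in
g (the group-1 variance uses n_1, the parallel of the group-0 form).

## Degrees of freedom, alternatives, adjustment

df = n − 4 requires n ≥ 5 animals with complete adjacent pairs.  One-sided
alternatives are supported ("greater" means group 1 exceeding group 0);
default two-sided.  No multiplicity adjustment is applied across time points
by default; an optional Holm step-down over the homologous p-values is
available in the scanner.

## Data handling

Input is long-format CSV (animal_id, group, time, volume).  Missing or
non-numeric volumes drop the row with a warning.  For each comparison the
"previous" time point is the immediately preceding *observed* time in
sorted order; irregular spacing gets no adjustment.  Pairing is
complete-case per adjacent pair: an animal missing either measurement is
excluded from that one test only (the formulas assume paired vectors and
prescribe no imputation rule; complete-case is our choice).  Group 0 is the
first-seen label unless mapped explicitly, and every output carries display
labels to keep the sign of D̂ unambiguous.  Volumes may be analyzed raw
(default, mm³) or natural-log transformed by flag.

A design is declared rank-deficient when its smallest singular value falls
below 1e−12 of the largest (a within-group-constant covariate is the
typical cause); the scanner then reports the t-test only, with a warning,
never substituting it for the homologous p-value.

## Monte-Carlo power engine

Each replicate draws y_prev ~ N(0,1) per animal and one error vector
ε ~ N(0, σ²), then forms **two response views sharing those draws**:

- **Calibrated view** (homologous test): the covariate is mean-centered
  within each group before responses are generated.  Centering enforces the
  calibration equality ρ_g σ-ratio (ȳ_{g,prev} − E Y_{g,prev}) = 0 in both
  groups, so the conditional means being compared differ only through β1.
  Consequences, both verified by test: the homologous power is exactly
  invariant to β2 and β3, and the statistic is an exact noncentral t with
  df 2m − 4 and noncentrality β1/(σ√(2/m)).  Without calibration the
  rejection rate also picks up replicate-to-replicate covariate-mean
  imbalance: higher apparent power under alternatives, but badly inflated
  type-I error when β2, β3 ≠ 0 under the null — the calibrated design is
  the honest one.
- **Marginal view** (pooled t-test): responses generated from the raw,
  uncentered covariate.  The t-test addresses the marginal hypothesis, and
  its data must carry the marginal group variances σ² + β2² and
  σ² + (β2+β3)².  Running the t-test on the calibrated view instead would
  strip the covariate's contribution from the mean difference while leaving
  it in the pooled variance, making the comparator spuriously conservative
  (observed rejection ≈ 0 under nulls with β2 = 1) — an unfair and
  miscalibrated benchmark.

With β2 = β3 = 0 the views coincide.  Rejection is p ≤ α (boundary has
probability zero).  A numerically singular replicate is redrawn once, then
counted as a non-rejection; with a continuous covariate this never occurs.

`analytic_power` supplies closed forms: the homologous noncentral t
(exact); the pooled t on the marginal view with β3 = 0 (exact, df 2m − 2,
variance σ² + β2²); and for β3 ≠ 0 an unequal-variance normal approximation
(flagged approximate, two-sided only).  Unsupported combinations raise
rather than silently approximate.

**Sample size.** The per-arm size is a free parameter; the default m = 7
(n = 14; df 10 homologous, 12 t-test) is the value at which the analytic
pooled-t powers across the (σ, β1) grid with β2 = β3 = 0 best match the
engine's reference operating points (calibration RMSE 0.025; the
neighboring sizes 6 and 8 both exceed 0.055).

**Randomness.** One root seed; each grid cell derives an independent
sub-stream by hashing the cell's parameter values (float bit patterns) into
a SeedSequence spawn key, so cell results are invariant to grid order and
reproducible bit-for-bit.

## Synthetic growth generator

`generate_growth_study` emulates the structure of real xenograft data: per
animal, log volume = intercept_i + slope_g·t + AR(1) residual over the
measurement grid (stationary, parameter φ, marginal SD `noise_sd`), then
exponentiated to mm³.  Defaults — 10 animals/arm, days
(3, 5, 7, 12, 14, 17, 19, 21, 24), start ≈ 4 mm³ at day 3, control slope
0.20/day with a −0.03 treated offset, φ = 0.95, noise SD 0.30 — place the
median adjacent-time within-group correlation around 0.8–0.95, the regime
where the homologous test's advantage is large.  The generator is a fixture
engine, not a kinetic model: it has log-linear growth only (no Gompertz
deceleration), no dropout or death process, no measurement floor, and
homoscedastic log-scale noise.  Passing tests on its output therefore
demonstrate correct behavior under linear-conditional-mean, serially
correlated, log-normal data — not robustness to the nonlinearities and
missingness of real studies.

## Numerical choices

- OLS via SVD (stable under near-collinearity); SSE computed as
  Y′Y − β̂′X′Y and clipped at zero against cancellation; agreement with the
  normal-equations solution to 1e−8 relative is enforced on
  well-conditioned data.
- Rank threshold 1e−12 relative; the singular-design diagnostic names the
  implicated column, preferring a covariate column when the null space is
  multi-dimensional.
- t tail probabilities via the regularized incomplete-beta t CDF
  (`scipy.special.stdtr`) for speed in simulation loops; identical to
  `scipy.stats.t` values.
- Zero-variance degenerate inputs: identical groups give D̂ = 0, p = 1;
  a constant within-group covariate yields ρ = NaN and a degenerate flag
  rather than a crash.

## Problem sizes used in validation

The test suite exercises the identities on 1000 randomized instances, null
calibration and oracle agreement at 10,000 replications per setting, the
headline power cells at 1000 replications, and the full 81-cell grid at 500
replications — sizes at which binomial noise is small relative to the
effects being checked while the whole suite completes in a couple of
minutes on one CPU.

## Known limitations

- Conditions on a single preceding time point only; multi-point or
  bidirectional conditioning and p-value combination across time points are
  out of scope.
- The conditional and marginal nulls differ at finite n; a user unwilling
  to accept the homologous reframing should read the t-test column.
- No robust/sandwich variance option; normal errors are assumed.
- The scanner reports ρ whenever both within-group variances are nonzero;
  it does not attempt to reproduce any particular table's missing-value
  conventions.
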