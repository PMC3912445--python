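# Methods

## The model

The package's growth law states that a fish's per-step length increment is
proportional to its remaining growth potential:

    dL = k · (L_max − L_s),      k ∈ [0, 1],  L_max > 0.

`L_s` is the current length, `L_max` the maximal length of the
individual/stock, and `k` a dimensionless environmental coefficient. Three
modelling commitments follow:

- **Time-free.** No age or calendar variable enters the dynamics; a "step" is
  whatever interval separates consecutive observations (a year for stock
  survey data, a day for laboratory fish) and is carried only as a metadata
  tag. This is what allows summing growth across all year-classes within one
  observation year.
- **Physical bounds.** `k < 0` would shrink the animal and `k > 1` would
  overshoot `L_max` in a single step; both are rejected at construction
  rather than clamped, so every trajectory is non-decreasing and bounded by
  `L_max`. `L_max` is a fixed value the increments actually reach (the gap
  decays geometrically, `L_max − L_n = (L_max − L0)(1 − k)^n`), not an
  asymptote of a time curve.
- **Environment lives in k.** Variation in food and temperature is expressed
  as variation in `k` — per step in projections, per age in the juvenile
  deviation analysis — never as a change to `L_max` within an analysis.

## Estimation

Rearranged, `dL = −k·L_s + k·L_max`: a line in the (length, increment) plane.
Cohorts are read off a year×age table's diagonals (a year-class born in `b`
has age `a` in year `b + a`); each consecutive-age adjacency yields a pair
`(L_a, dL_a)` with `dL_a = L_(a+1) − L_a`, paired deliberately with the
start-of-interval length because the law is written with the length before
the increment. Negative observed increments are retained for regression
(dropping them would bias the slope toward zero) but flagged.

Fits are ordinary least squares (via statsmodels): the line, and a free
quadratic `dL = c2·L² + c1·L + c0` as the alternative. Derived parameters
`k = −slope` and `L_max = −intercept/slope` are populated only when the slope
is negative; a non-negative slope means the law cannot hold on those data and
the parameters are reported as undefined rather than negative. Standard
errors for `k` and `L_max` come from the delta method on the
(intercept, slope) covariance; intervals use the t distribution with `n − 2`
degrees of freedom.

Averaging across year-classes ("per-age-average" pooling) is unweighted: for
each age, the plain mean of `L_a` and of `dL_a` over the cohorts observed at
that age. Raw-union pooling is available as an alternative.

### Model comparison

The line is nested in the quadratic, so the comparison is the
extra-sum-of-squares F-test: `F = (SS_lin − SS_quad) / (SS_quad/(n−3))` with
(1, n−3) degrees of freedom and an upper-tail p-value — the standard
variance-ratio test behind "model X preferred (p = …)" output in commercial
curve-fitting software. Numerically exact ties (both residual sums below
1e-12 of the total SS) resolve toward the simpler linear model; an exact
quadratic over an inexact line reports p = 0. A small-sample AICc comparison
is available behind a flag but is not the default.

### Deviating juvenile ages

In wild stocks the youngest one or two ages sometimes grow below the line
fitted to older fish (e.g. juveniles in colder nursery areas). The detector
iteratively drops the youngest age while the linear fit on the remaining
pairs has R² below a threshold (default 0.98, the fit quality older ages
reach in well-behaved stocks) and at least `min_points` (default 3) pairs
remain, returning the largest qualifying suffix. Only a prefix of youngest
ages is ever excluded — the procedure is a screen for juvenile deviation,
not general outlier pruning — and it is idempotent on its own output. If no
suffix qualifies the full series is returned flagged.

Excluded ages then receive an individual coefficient
`k_a = dL_a / (L_max − L_a)` — the slope of the straight line from the
observed point to (L_max, 0) — against a shared `L_max` taken as the
unweighted mean of the per-cohort core-fit estimates. Negative `dL_a` clamps
to `k_a = 0` with a flag: unlike a regression, a single-point ratio has no
context to cancel noise, and a negative k is unphysical.

## Projection and biomass

Forward projection applies the recursion with a per-step k series
(`EnvironmentalKSeries`, each value validated into [0, 1]; a series shorter
than the requested steps is an error, never recycled). Weight converts
through Fulton's condition relation `W = c·L³` with `c` in declared units
(weight per length³; no implicit conversions), and stock biomass is
`Σ abundance·c·L³` over the year-classes present in the same step. Mortality
and recruitment are exogenous per-step abundance multipliers; whether the
multiplier applies before or after within-step growth is a flag the caller
sets explicitly, with no default endorsement of either ordering beyond
"before-growth" as the argument default.

## The synthetic generator

The generator emulates the data layout this analysis consumes: a run of
year-classes, each grown by the law itself from a first-age length
(default: one application of the law from zero length, `L(age_min) =
k·L_max`), laid onto the year×age grid, with two independent perturbation
channels:

- **per-age k overrides**, e.g. `{1: 0.15, 2: 0.15}`, reproducing juvenile
  growth suppression with a known truth for detection tests;
- **observation noise**: iid additive Gaussian on each observed mean length
  (the quantity surveys actually report), clipped to a tiny positive floor
  that realistic noise never reaches.

Defaults mirror a spring-spawning-herring analysis scale — ages 1–9,
k = 0.3 yr⁻¹, L_max = 354 mm, 11 year-classes, lengths in mm — so synthetic
output is directly comparable to published increment-by-length plots.
Randomness is NumPy's PCG64, fully determined by the spec seed and recorded
in the truth sidecar.

What the generator does **not** emulate: within-age length distributions and
age-reading error, survey selectivity and catchability, cohort-to-cohort
`L_max` variation, and autocorrelated environmental forcing. Passing tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to every failure mode of real survey
data.

### A note on confidence-interval coverage

The two noise channels have different statistical consequences. Noise on
observed lengths propagates into increments as `dL_a err = e_(a+1) − e_a`:
adjacent increments share a length observation, so their errors are
negatively correlated, and nominal OLS/delta intervals become conservative —
measured coverage is ≈99% at 5%-of-mean-increment noise, never below
nominal. The coverage *calibration* study (acceptance test and script)
therefore uses iid Gaussian noise on the increments themselves — the error
model the delta-method interval assumes, and the only one under which a
two-sided coverage band is a meaningful check — where coverage lands at
≈95%. A separate test documents the conservative (never anti-conservative)
behaviour under the survey-style length-noise channel.

## Numerical choices

- Floating comparisons against `L_max` use an absolute tolerance of 1e-9
  length units; stepping clamps at `L_max` exactly.
- R² is computed against the mean-increment null and clipped to [0, 1]; a
  zero total SS (all increments identical) reports R² = 1 for an exact fit
  and 0 otherwise.
- Exact-fit detection in the F-test uses a relative residual threshold of
  1e-12 of the total SS.
- Table text format writes floats with Python's shortest round-trip repr, so
  writer→reader is bit-exact.
- Validation studies use herring-scale conditions: 9 ages per cohort,
  noiseless identifiability checked over k ∈ [0.05, 0.6] and
  L_max ∈ [50, 1000] (above k ≈ 0.6 the oldest ages sit within floating
  rounding of `L_max` and the 1e-9 exactness claim stops being about the
  estimator), detection over k ∈ [0.25, 0.35] with juvenile k halved,
  F-test calibration at 10⁴ replicates of 9 pairs. These sizes keep the full
  validation under half a minute on one core.

## Known limitations

- `L` appears on both axes of the regression (`dL` contains `L_(a+1)`), an
  errors-in-variables situation the OLS estimator ignores; at survey-scale
  noise the attenuation is negligible, but it is not corrected.
- No weighting by sample size or survey design; per-age averaging is
  unweighted.
- The comparison test assumes iid Gaussian residuals; with length-sourced
  noise the mild negative correlation makes it slightly conservative.
- Sub-annual data reuse the same machinery with "age" as observation index;
  `normalized_increments` divides increments by the elapsed interval for
  unevenly spaced observations, but no finer time structure is modelled.
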