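# Methods

`bcsense` compares two ways of measuring body condition score (BCS) in
dairy cows — an automated overhead 3D camera that scores each cow at every
milking, and a panel of trained visual scorers working weekly — on the
footing that matters for research use: how reliably each method detects a
real change in a cow over time, or a real difference between cows, at the
scale of a cow-by-week mean score.

## The measurement model

Every score is modelled as a Gaussian crossed random-effects observation

    y = mu + (fixed trend) + sum_i u_i + e,     u_i ~ N(0, sigma_i^2),

with one random term per element of the sampling structure.  Factor
letters: W week, D day within week, M milking (AM/PM), A animal, C camera
unit, S scorer, and a residual.  The camera model carries the 15
non-residual terms W, A, C, WD, WA, WC, AC, WDM, WDA, WDC, WAC, WDMA,
WDMC, WDAC, WDMAC; the visual model carries W, A, S, WA, WS, AS.  Three of
the components describe the cows rather than the instruments — W (herd-wide
week-to-week wobble), A (between-animal differences) and WA (animal-specific
week-to-week change) — and everything else is measurement structure.

## Sensitivity

For a cow-by-week mean, the *actual* (signal) variance is

* change over time within a cow: `sigma_a^2 = sigma_W^2 + sigma_WA^2`
* difference between cows in a week: `sigma_a^2 = sigma_A^2 + sigma_WA^2`

and the *error* variance is the design-weighted sum of the error
components, `sigma_m^2 = sum_i sigma_i^2 / n_i`, where `n_i` counts the
independent draws of that effect averaged into one cow-week mean.  Under
the reference design the camera mean averages 7 days x 2 milkings = 14
scores across 2 units, giving divisors 7 for week.day-type terms, 2 for
camera-crossed weekly terms, and 14 for milking-level terms and the
residual; the visual mean averages 3 scorers on one day, giving divisor 3
throughout.  Main effects of camera unit and scorer are excluded from
`sigma_m`: a consistent per-device offset acts as a block effect (scorer is
orthogonal to cow-by-week in this design; a camera offset can be blocked
out) and does not corrupt within-week or between-week comparisons.

Sensitivity is the Mandel–Stiehler ratio `Theta = sigma_a / sigma_m`.  It
is dimensionless and invariant to any affine rescaling of the score scale,
which makes it a fair criterion across instruments calibrated to different
scales.  Two methods are compared by `RS = Theta_1 / Theta_2`; because
`sigma_m^2` is inversely proportional to the number of independent
samplers, the weaker method needs `RS^2` times its current sampling
intensity to catch up.  With a rate of change `beta` (BCS/month, the pooled
OLS slope of cow-week means on time), a change becomes detectable — taken
as `3 sigma_m` — after `t = 3 sigma_m / |beta|` months.  Months are
converted to days at 30.44 d/month (365.25/12); with the reference rates
(-0.18 / -0.19 / -0.17 BCS/month) this reproduces the reference detection
times to within one day (21 / 13 vs 12 / 45 vs 44 days for raw camera,
refined camera, visual).

## Refinement of raw camera series

Camera records are first validity-filtered (scores <= 0 are hardware
failures, ~8% in the reference herd).  Then, per cow, a robust loess
(span 0.5, local quadratic, tricube neighbourhood weights, 4 rounds of
bisquare down-weighting — the "symmetric" family) is fitted to score vs
time, with AM/PM observations offset to 0.25/0.75 of a day.  Observations
whose residuals fall outside Tukey's fences (1.5 x IQR beyond the
quartiles, type-7 quartiles, computed per cow) are removed.  One pass only.
Fences are per-cow by default because the smoother is fitted per cow;
pooling residuals across cows is available as an option.  Series too short
for a quadratic fit (< 4 points) are kept unrefined and logged.

The vendor-style alternative — a trailing 7-day rolling mean that discards
the top and bottom 20% of each window (trim count `floor(0.2 n)` per tail)
— is provided for comparison; it trims a fixed share of data whether or not
anything is outlying and ignores trend within the window.

## REML estimation

Variance components are estimated by exact restricted maximum likelihood.
The implementation is a safeguarded average-information (AI) algorithm:
moment-based starting values, one EM warm-up step, then AI updates with
step halving so the restricted log-likelihood never decreases; components
are constrained to `sigma^2 >= 0` with an active set, so boundary estimates
are reported as exact zeros.  Convergence is declared when the relative
change in restricted log-likelihood falls below 1e-8.  The likelihood is
evaluated in observation space (V assembled from precomputed level-match
indices, one Cholesky per evaluation, lower-triangle storage throughout),
which is exact and practical at herd scale (a few thousand records, ~10 s
per camera fit, milliseconds for toy designs).  The procedure is fully
deterministic; on balanced designs with interior solutions it agrees with
closed-form expected-mean-squares estimators to 1e-4 relative and with
statsmodels' MixedLM on one-way layouts to 1e-5.

Aliasing is diagnosed before fitting: any term whose realized levels each
contain at most one observation has an identity-match matrix and is
indistinguishable from the residual.  With one camera pass per
cow-milking this applies to WDMA and WDMAC, which are constrained to zero;
the residual then estimates `sigma_eps^2 + sigma_WDMA^2 + sigma_WDMAC^2`.
Terms with a single realized level (confounded with the intercept) and
pairs of terms inducing identical partitions are likewise flagged.

The fixed part is an intercept by default.  When the data carry a
systematic trend — as the synthetic herd always does — a linear time
covariate can be added (`fixed_trend=True`, used by the pipeline);
otherwise the trend variance is absorbed into the week component
(~0.009 BCS^2 at the default slope over 7 weeks, a ~47% inflation of the
refined-camera week component), which would misstate the week-to-week
wobble the generator actually drew.

## Synthetic herd generator

No raw data from the reference study are available, so the generator
recreates its design: 32 cows x 7 weeks, camera scores at 14
milkings/cow-week on 2 self-selected units (uniform random per milking,
which makes camera non-orthogonal to animal and time, as in the study),
and 3 scorers on one day per week.  Biological effects (W, A, WA, trend)
are drawn once per herd and shared by both methods — both instruments watch
the same cows — while measurement effects and residuals are method-specific
and independent.  Defaults: grand mean 4.5, trend -0.19 BCS/month,
refined-camera reference components for the biological terms and camera
measurement terms, visual reference components for the scorer terms.  All
effects are Gaussian; the trend is linear.  Reproducibility is exact: one
seed determines every draw, and zeroing a single component leaves all other
realizations unchanged (fixed stream layout).

Camera contamination is generated separately, with truth labels retained:
each record is independently invalid with probability 0.08 (replaced by 0
or a uniform(-1,0) draw; only the sign matters downstream) and an outlier
with probability 0.07 (shifted by ±4 reference SDs).  The outlier unit is
the *raw-data* single-measurement residual SD of the reference study
(sqrt(0.0218) ≈ 0.15 BCS), giving spikes of ≈0.6 BCS: outliers are gross
failures of the raw signal, and expressing them in units of the much
smaller refined residual would make "4 SD" spikes smaller than the
dispersion the outlier rule actually sees (loess residuals also carry the
week-level wobble the smoother cannot follow, ≈0.11 BCS).  A consequence
worth knowing: the contaminated process has a somewhat heavier tail than
the reference raw data (implied raw residual variance ≈0.031 vs 0.0218);
matching that variance exactly would need a multiple of ≈3.1 instead of 4,
at which point spikes sit near the Tukey fence and detection becomes
marginal.  The raw > refined
residual-variance ordering that motivates refinement is preserved under
either choice.

What the generator does not emulate: lactation-curve nonlinearity beyond a
linear trend, missed transponder reads, scorer drift over time, and the
0.25-point discreteness of visual scores.  Tests passing on this generator
therefore demonstrate correctness of the estimators under the stated
model, not robustness to those real-data features.

## Problem sizes used in the test suite

Parameter-recovery checks run at the full study design (32 cows x 7 weeks,
20 seeds).  Refinement-efficacy checks (which need two REML fits per seed)
run at 16 cows x 5 weeks, 20 seeds.  Method-of-moments generator checks run
at 10x animals and weeks (320 x 70).  End-to-end pipeline and invariance
checks use an 8-cow x 4-week herd.

## Numerical choices and edge cases

* Quartiles: linear interpolation of order statistics (type 7); stated
  because the convention changes Tukey flags on tiny samples.
* Loess ties in time are tolerated; a zero neighbourhood radius falls back
  to uniform kernel weights, and a fully down-weighted neighbourhood falls
  back to kernel-only weights.
* `tukey_outliers` with fewer than 4 residuals flags nothing and warns.
* A constant response short-circuits REML to all-zero components.
* Degenerate sensitivity inputs raise (`sigma_m = 0`) or return infinity
  (`beta = 0` with `sigma_m > 0`), never silently produce numbers.
* Scale conversion between BCS scales is an affine map with positive slope
  supplied by the user; the widely used 1-10 to 1-8 conversion coefficients
  are configuration, not package constants.
* Bland–Altman "95% range" is mean ± 1.96 SD of differences (limits of
  agreement); the empirical 2.5/97.5 percentile range is reported
  alongside.  Differences are oriented camera − visual.  Sample (n−1)
  moments throughout, including Lin's concordance coefficient.

## Known limitations

* The residual is only identified jointly with fully-aliased interaction
  terms (see aliasing above); this is a property of the design, not the
  estimator.
* With 7 weeks the week variance component is estimated on ~6 effective
  degrees of freedom; single-study estimates of sigma_W^2 are intrinsically
  noisy (coefficient of variation ≈ 58%), which propagates into
  change-over-time sensitivities.
* Relative sensitivities computed from rounded reference components can
  differ from values derived from unrounded fits in the last printed digit.
* The AI-REML works in dense observation space: fine for thousands of
  records, unsuitable for datasets orders of magnitude larger.
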