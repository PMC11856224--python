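# Methods

## Thermal performance models

Two Ratkowsky-family curves describe the temperature dependence of fungal
development, both with cardinal temperatures T₁ (lower) and T₂ (upper) at
which the rate is zero:

- `ratkowsky1` — r(T) = cc·[k1·(T−T₁)·(1−exp(k2·(T−T₂)))]², used for
  proportion-scale responses (7-day nymphal mortality).  The scale factor
  `cc` sits **outside** the square.  This placement is deliberate: with the
  bundled virulence parameters the outer-cc form evaluates to 0.607 at
  25 °C and 0.680 at 30 °C — exactly the proportion scale of the observed
  mortalities the curve describes — whereas placing cc inside the square
  gives values above 2, impossible for a proportion.
- `ratkowsky2` — r(T) = [cc·(T−T₁)·(1−exp(k·(T−T₂)))]², used for colony
  growth rate.  Its response units are arbitrary (the growth data they
  summarize are colony areas in mm²), so only the argmax is interpreted.

The squared expressions are mathematically positive outside [T₁, T₂]; both
evaluators return exactly 0 there, since no growth or infection occurs
beyond the cardinal temperatures.  Proportions are additionally capped at
1.0 when mapped to percent mortality.

The thermal optimum is found deterministically: a 0.1 °C grid scan
bracketing the maximum, then bounded scalar minimization of the negated
response to a 0.001 °C tolerance.  Tests verify agreement with an
exhaustive 0.001 °C scan.

## Time–mortality curves and LT50

Cumulative mortality F(t) uses standard dose–response parameterizations,
each with plateau d ∈ [0, 1], steepness b > 0 and location e:

| family       | F(t)                       |
|--------------|----------------------------|
| logistic     | d / (1 + exp(−b(t−e)))     |
| log-logistic | d / (1 + (t/e)^(−b))       |
| log-normal   | d · Φ(b · ln(t/e))         |
| weibull      | d · (1 − exp(−(t/e)^b))    |
| gompertz     | d · exp(−exp(−b(t−e)))     |

Each family has a closed-form inverse, so the median lethal time solves
F(t) = 0.5 exactly.  LT50 is defined at the **absolute** 50% mortality
level, not 50% of the plateau: when the fitted plateau d ≤ 0.5 the LT50 is
reported as not estimated, which is how assays dash out treatments whose
mortality never reaches half.

Confidence intervals are a percentile bootstrap (B = 999 by default,
seeded) resampling whole replicates with replacement and refitting; the
reported interval is widened minimally if the percentile bounds exclude
the point estimate, so the (lt50, ci_low, ci_high) triple is always
internally consistent.  A delta-method interval from the original fitting
software would need the original replicate data, which is not published;
the bootstrap is this package's documented substitute.  Two LT50s are
declared different when their intervals are disjoint.

No spontaneous-mortality (Abbott) correction is applied by default — raw
mortality proportions are fitted, with controls handled statistically — but
`abbott_correction` is provided as a utility.

## Fitting and model selection

All fits are bounded least squares (scipy `least_squares`, trust-region
reflective) from 20 Latin-hypercube starting points over the parameter
bounds (seeded, deterministic) plus one data-driven heuristic start; the
Ratkowsky surface is multimodal in (T₁, T₂), which single-start optimizers
routinely get wrong.  Default bounds: T₁ ∈ [0, 25] °C, T₂ ∈ [25, 45] °C,
positive scale/rate parameters ≤ 100; time-course b ≤ 50, d ∈ [0, 1],
e ∈ (0, 60] days.  Proportions are fitted untransformed (no arcsine or
logit), matching the assay practice the package emulates; callers can
transform responses before fitting if desired.

Fit statistics follow the least-squares conventions R² = 1 − RSS/TSS,
adjusted R² = 1 − (1−R²)(n−1)/(n−k−1), RMSE = √(RSS/n) and
AIC = n·ln(RSS/n) + 2(k+1), counting the error variance among the
parameters.  A perfect fit reports AIC = −∞.  Ranking is ascending AIC,
ties by descending adjusted R², then ascending RSS; non-converged fits sort
last.

Curve comparison fits one pooled curve and one curve per group and forms
the Gaussian likelihood-ratio statistic n_total·ln(RSS_pooled/RSS_sep),
referred to a chi-square with df equal to the parameters freed by the
separate fit.  The separate fits are seeded with the pooled solution as an
extra start, so nesting (RSS_sep ≤ RSS_pooled, statistic ≥ 0) holds in
practice as well as in theory.  This pooled-vs-separate LR is an
interpretation of "chi-square comparison of two curves"; comparing a single
parameter with the others shared is a different (not implemented) test.

## Spatial projection

Monthly minimum/maximum temperature rasters are read from ESRI ASCII
(`.asc`) or little-endian flat-binary (`.flt` + `.hdr`) files; big-endian
(MSBFIRST) payloads are rejected explicitly rather than silently misread.
Grids are north-up matrices (rows = latitude, cols = longitude) with a
nodata sentinel (−9999 by default) that propagates through all arithmetic;
ASCII output renders 6 significant digits with a locale-independent "."
decimal.

For each selected month the per-cell evaluation temperature is chosen by a
policy — default the midpoint (Tmin+Tmax)/2, with `min`, `max` and
`mean_of_two` (average of the two evaluations) available — the model is
evaluated, and the monthly responses are averaged arithmetically over the
season (October–March by default, the soybean growing season in the region
the package targets).  How min and max "should" be combined is genuinely
underdetermined, hence the policy is configurable and recorded in the
output metadata.

Percent mortality is classified into half-open bands [lo, hi) with default
edges (10, 25, 60) and labels low / moderate / high / very high.  Only the
10–25 band and the >60 threshold are anchored in reported results; placing
the high/very-high boundary at 60 with high = [25, 60) is this package's
reading of a four-band legend and is configurable.

Hourly exposure summaries count hours per day in contiguous half-open
temperature bands (−∞,15], (15,20], (20,25], (25,30], (30,35], (35,∞) °C —
a reading exactly on an edge counts in the band below-or-equal — and report
per-month mean hours/day.  Per-day counts always sum to the hours actually
observed that day (gaps count as missing, not as zero).

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate the
statistical structure the analysis assumes:

- **Growth**: colony area grows linearly at the thermal-response rate with
  additive Gaussian noise (default sd 10 mm², of the order of
  between-plate variation in colony-area assays), floored at 0.  Length
  and width are emitted via the ellipse convention area = π·L·W/4 with
  L = W (the axis-to-area conversion is otherwise unstated).
- **Mortality**: each replicate of n nymphs (default 60, a realistic
  per-leaf count; the true assay n is unpublished) follows a logistic
  cumulative curve whose plateau is the thermal response at the treatment
  temperature for constant regimes, or at the ambient mean for pulse and
  daily-alternating regimes (temperature-insensitive after penetration).
  The logistic location is calibrated so the absolute-50% crossing equals
  the prescribed LT50 truth; steepness defaults to 1.5 /day so the 3–7 day
  assessment window spans the rise of the curve.  Dead counts accrue by
  conditional binomial increments (monotone, marginally Binomial(n,
  F(day))); an untreated control series uses a daily spontaneous hazard of
  0.005, and each fungus-killed cadaver shows confirmatory sporulation
  with probability 0.95.
- **Climate**: midpoint temperature varies linearly with latitude and
  sinusoidally with month (peak in January, austral summer); Tmin/Tmax
  straddle the midpoint by a uniform random 6–12 °C diurnal range.
  Because the range is symmetric, the midpoint field is deterministic
  given the seed, so the generator also returns the analytically true
  performance class of every cell for truth-table tests.

What the generators do **not** emulate: humidity, solar radiation and
rainfall effects; replicate-level random effects beyond binomial sampling;
spatially correlated weather; real topography or coastlines.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the assumed model, not field validity of the predictions.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale problems chosen as the smallest
sizes at which the statistical claims are meaningful: 20-seed recovery
loops with 60 nymphs × 4 replicates per regime, 50-dataset noisy-recovery
medians, and 200×200 projection grids.  Optimum finding is deterministic;
all stochastic steps take explicit integer seeds.  Degenerate inputs are
handled explicitly: all-zero responses flag non-convergence (or cc ≈ 0),
zero total sum of squares raises rather than reporting a meaningless R²,
and an exactly-zero separate-fit RSS with nonzero pooled RSS reports an
infinite comparison statistic with p = 0.

## Known limitations

- The LT50 bootstrap resamples replicates only (4 per regime in the
  emulated design), so interval endpoints are coarse at that replication
  level.
- The chi-square curve comparison relies on Gaussian-error asymptotics;
  with binomial proportions at small n its p-values are approximate.
- Spatial projection assumes all layers share geometry; there is no
  reprojection, and cartography is out of scope.
- Published LT50 tables cannot be reproduced numerically because the
  underlying daily counts are unpublished; generator-truth recovery tests
  stand in for them.
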