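# Methods

This note documents the models, the synthetic-cohort generator, the
numerical choices, and the known limitations of `perifield`.

## 1. Psychometric model

Performance in the two-alternative forced-choice (2AFC) detection task is
modeled with a Weibull psychometric function of Michelson contrast `x`:

```
psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-(x / m)^beta))
```

with guess rate `gamma = 0.5`, slope `beta = 3.5`, and lapse rate
`lambda = 0.02` held fixed; only the scale `m` is estimated. The *threshold*
reported everywhere is the contrast at the staircase's targeted performance
level, `psi(threshold) = 0.81`, obtained in closed form
(`pf_quantile`). With the default shape this places the threshold at
`1.0107 * m`.

Fixing the shape is deliberate: with 80 trials per condition cell, slope and
lapse are poorly constrained, and letting them float trades variance in the
quantity of interest (the threshold) for parameters that are not analyzed.

## 2. Adaptive procedure: paired running-fit staircases

Each condition cell is measured with **two interleaved 40-trial running-fit
staircases**. A running fit re-estimates the threshold after every trial and
places the next stimulus at the current estimate:

- The estimate is the maximum a posteriori (MAP) value of `log10 m` under a
  Gaussian prior with SD 0.2 dex, centered on the staircase's starting
  contrast (in practice, 1.5x a coarse pre-estimate of the observer's
  threshold, mimicking a brief contrast-adjustment pre-test).
- Each staircase opens with one unscored orienting trial at the starting
  contrast; it familiarizes the observer with the stimulus and is excluded
  from all fits. A cell therefore logs 82 trials of which 80 are scored.
- Placements are clipped to the displayable range [0.001, 1].

After both staircases finish, the cell's threshold is **re-estimated from
the pooled 80 scored trials with the identical MAP fit**. Because the
sequential MAP fit conditions on exactly the pooled data at its last trial,
the pooled re-estimate equals the terminal running-fit value; the pooling
step matters when combining staircases or refitting logs read from disk. A
prior-free one-shot maximum-likelihood variant (`ml_threshold`) is provided
for sensitivity analyses.

**Numerics.** The posterior over `log10 m` is evaluated on a 301-point grid
spanning [-4, 0] (0.0133 dex resolution); the argmax is refined by parabolic
interpolation through the three surrounding grid points, giving sub-grid
accuracy at negligible cost. The log-likelihood is assembled once as a
(grid x trials) matrix of per-trial terms, so sequential updates and
bootstrap refits reduce to matrix products.

**Reliability screen.** Each cell's threshold gets a nonparametric bootstrap
standard error (default B = 500 resamples of the 80 scored trials, refit by
the same MAP rule, SE taken on `log10` threshold). Cells with SE > 0.2 dex,
or with degenerate data (all responses identical, or fewer than two distinct
contrasts), are flagged unreliable and excluded downstream. The bootstrap is
vectorized by drawing multinomial *counts* over trials and multiplying them
into the per-trial likelihood-term matrix.

**Calibration.** Evaluating the generating psychometric function at
recovered thresholds over >= 500 replicates yields a mean of ~81% correct
(81.0% at seed 1), confirming the procedure converges on its targeted
performance level with negligible bias at the full trial budget.

## 3. Threshold versus spacing: the clipped exponential

For masking and crowding, thresholds at center-to-center spacings `x`
(five spacings, 0.2-0.6 of target eccentricity) are fitted with

```
y(x) = alpha + (1 - alpha) * exp(-s * (x - t))   for x >= t
y(x) = 1                                          for x <  t
```

- `alpha` in [0.01, 1] is the **baseline contrast** (`ybase`);
- `t >= 0` is the spacing at which the threshold reaches the ceiling of 1;
- `s` in (0, 25] is the spatial decay rate.

The **critical distance** is the spacing at which the elevation above
baseline has fallen to 10% of its ceiling-to-baseline range:

```
xcrit = t + ln(10) / s        (because exp(-s * (xcrit - t)) = 0.1)
```

Two exact identities follow and are enforced as invariants: `y(t) = 1`,
and `y(xcrit) - ybase = 0.1 * (1 - ybase)`.

Fits use constrained trust-region least squares with multi-start (three
deterministic starts plus ten jittered starts from a fixed-seed generator;
ties resolved toward the smallest `s`). Fits require at least four distinct
spacings, must pass an adjusted-R² screen (>= 0.7), and a baseline pinned at
the lower bound `alpha = 0.01` marks the baseline measure as unusable. On
small instances the optimizer's objective matches a dense brute-force grid
search to 1e-6 (tested).

## 4. Grouping: clipped-line over eccentricity

Contour-integration thresholds are flat out to a critical eccentricity and
then rise linearly with the **farthest element's eccentricity**
`x = hypot(E + d, d)` (target eccentricity `E`, grid spread `d`):

```
y(x) = b + m * max(0, x - x0),    m >= 0
```

The breakpoint `x0` is profiled: for each candidate `x0`, `b` and `m` are
the closed-form least-squares solution (slope clamped at 0), and the best
`x0` from a 201-point grid is refined by bounded scalar minimization. The
**critical eccentricity** is where the threshold first exceeds baseline by
10%: `xcrit_ecc = x0 + 0.1 * b / m` (undefined for flat fits, `m = 0`).

## 5. Contrast sensitivity function

Sensitivity (1/threshold) versus spatial frequency `f` is fitted with
`S(f) = (a + b f) * exp(-c f)`. Derived quantities: peak frequency
`fmax = 1/c - a/b`, peak sensitivity `smax = S(fmax)`, the high-frequency
half-height cutoff (Brent root-finding on `S(f) = smax / 2` above the peak,
verified against dense grid search to 1e-4), and the high-frequency
half-bandwidth `sf_cutoff - fmax`.

## 6. Normalization, exclusions, and correlation

Before correlating across participants, measures are made comparable across
retinal locations:

- `critical_distance_frac` — `xcrit` divided by eccentricity (Bouma-style
  scaling);
- `baseline_contrast_norm` — `ybase` divided by 1, 2 and 3 at 3.5, 7.0 and
  10.5 deg, reflecting the roughly linear growth of contrast thresholds over
  this range.

Exclusion rules, applied in order and logged per measure: `unreliable_fit`
(adjusted R² < 0.7, or upstream bootstrap SE > 0.2), `at_fit_limit`
(baseline pinned at `alpha = 0.01`), `exceeds_tested_range`
(critical-distance fraction above the largest tested spread, 0.6),
`non_finite`.

Associations between measures observed at the same eccentricities within
the same participants use the **repeated-measures correlation** (common-slope
ANCOVA): both variables are centered within participant, a single shared
slope is fitted, and

```
r_rm = sign(slope) * sqrt(SS_measure / (SS_measure + SS_error)),
df   = n_obs - n_subjects - 1,
```

with the p-value from `F(1, df)`. The implementation matches an independent
indicator-variable least-squares oracle to 1e-10 and `pingouin.rm_corr`
exactly (tested), and its type-I error at alpha = 0.01 is calibrated within
Monte-Carlo error over 2,000 null replicates (tested). One-per-participant
quantities (e.g. grouping baseline versus critical eccentricity) use the
plain Pearson correlation with df = n - 2. Significance is evaluated at
alpha = 0.01 throughout.

## 7. Synthetic cohort generator

The generator produces observers whose ground truth is known exactly, so the
full chain (staircase -> pooled estimate -> curve fit -> normalization ->
correlation) can be validated by parameter recovery.

Population means: masking baselines (0.030, 0.060, 0.090) at (3.5, 7.0,
10.5) deg, crowding baselines 2.8 contrast points higher; critical-distance
fractions 0.20 (collinear masking, crowding) and 0.17 (orthogonal masking);
grouping clipped line b = 0.063, slope 0.042, breakpoint 10.0 deg; CSF
(a, b, c) = (2.0, 60.0, 0.45). Between-participant variation is log-normal:
SD 0.15 on baselines, 0.10 on critical-distance fractions, 0.25 on grouping
slope, 0.08 on breakpoint.

Given a target `xcrit`, the generating curve's free split between `t` and
`s` is fixed as `t = 0.3 * xcrit`, `s = ln(10) / (0.7 * xcrit)`. This
"steep rise near the critical distance, flat near baseline" shape matches
typical spacing data and keeps the fitted `alpha` estimator nearly unbiased
at realistic measurement noise; with `t = 0` the slow decay leaves only one
tested spacing near asymptote and skews recovered baselines upward.

Each cell's staircase starts at 1.5x a noisy per-observer contrast proxy
(the collinear masking baseline with 0.1-dex noise), emulating the
adjustment pre-test. All randomness descends from one `SeedSequence` spawned
per stage, so a run is a pure function of its configuration.

**Recovery (tested):** on a 40-participant cohort, the cohort-median
recovered `ybase` is within 5% and `xcrit` within 10% of the generating
medians in every task x eccentricity, and every planned correlation analysis
survives the exclusion rules.

## 8. Limitations

- The psychometric shape (slope, lapse, guess) is assumed known and shared;
  misspecification biases thresholds, though the 81%-point parameterization
  is first-order robust to slope errors.
- The exponential spacing model and the clipped line are descriptive
  summaries, not mechanistic models; `xcrit` inherits the arbitrariness of
  the 10% criterion.
- Baseline normalization by fixed divisors (1, 2, 3) assumes linear growth
  of contrast thresholds with eccentricity; other scalings would change the
  normalized baselines but not within-participant correlation structure
  driven by shared factors.
- Simulated observers are stationary: no learning, fatigue, or serial
  dependence; bootstrap SEs are therefore mildly optimistic relative to real
  data.
- With five tested spacings, critical-distance fractions near the upper
  tested value (0.6) are extrapolations; the exclusion rules drop them
  rather than model them.
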