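# Methods

This note records the statistical model behind `cliffcensus`, the
numerical choices made where the procedure left room, and what the
synthetic experiments do and do not demonstrate.

## Census model

A cliff wall is partitioned into `n` square grid cells (10 m side by
default; geometry is metadata only — no spatial statistics use it).
Cell `i` carries an integer count `x_i` of *visual units*, the plant
units an observer can distinguish through a telescope. Border cells
with little rock are flagged excluded and ignored everywhere; exclusion
is by an explicit id list (the field decision is visual), with an
optional rock-fraction threshold as a convenience that is off by
default. Counts are modelled as i.i.d. draws from a count distribution
— a *superpopulation* view: the realised wall is one draw from the
species' cell-occupancy process. This is the assumption that lets an
incomplete census estimate the total, and it is also the main
limitation: real walls have spatial aggregation beyond what an i.i.d.
Negative Binomial captures (see Limitations).

## Correction factor

Observer `o` in year `y` counts `n_pairs` calibration areas twice:
`low` (20×, the survey lens) and `high` (60× or a true count). The CF
is the arithmetic mean of the ratios `high/low` — individuals per
visual unit — so the corrected total is `CF × Σ x_i`. The reciprocal
orientation (`low/high`, a shrink factor) is reported alongside for
traceability, but only the `high/low` mean is ever applied, because it
is the multiplier consistent with applying "the average" to recorded
visual units.

Design choices:

* The ratios are screened with a Shapiro–Wilk test at the analysis
  alpha (default 0.05). Failure (or fewer than 30 pairs) is a recorded
  warning, not an error: the protocol prescribes no alternative
  estimator, and the analyst should see the flag rather than have the
  batch die. A zero-variance sample passes trivially with a warning.
* Pairs with a zero low-magnification count have an undefined ratio and
  are dropped with a warning in batch estimation (an explicit
  `compute_ratios` call on such a pair raises).
* CFs are stored per observer and year; they are not transferable.

## Distribution fitting

Three families, all on support {0, 1, 2, …}:

| family | parameters | mean | variance |
|---|---|---|---|
| Poisson | λ | λ | λ |
| Geometric (failures) | p | (1−p)/p | (1−p)/p² |
| Negative Binomial | size r, mean μ | μ | μ + μ²/r |

The geometric uses the *failures-before-first-success* convention
(support starting at 0), matching the convention of the R fitting
ecosystem this workflow is usually run in; the shifted variant would
change p̂. The NB uses the (size, mean) parameterisation with a
converter to (size, prob).

MLEs: λ̂ and μ̂ are the sample mean; geometric p̂ = 1/(1 + mean); the NB
dispersion r̂ maximises the profile log-likelihood over log r
(bounded scalar minimisation, xatol 1e-10, bounds 1e-4…1e6).
Equidispersed data drive r̂ to the upper bound; the fit is returned
flagged `boundary=True` — it *is* the Poisson limit, and AIC then
prefers the Poisson on the parameter penalty, which is the correct
resolution rather than an error. All three MLEs equate the model mean
to the sample mean; this identity is load-bearing (see the expansion
estimator) and is property-tested.

Goodness of fit: observed count classes 0…max are compared with
expected frequencies from the fitted model, with an open class above
the maximum. Classes are pooled from the largest downward until both
the open tail and the class adjacent to it have expected frequency ≥ 5
(the classical rule of thumb; the pooling threshold is configurable).
df = classes − 1 − (estimated parameters), floored at 1; if pooling
leaves ≤ 2 classes the p-value is reported with a low-resolution
warning rather than suppressed. A χ² rejection flags a family but does
not remove it from the AIC/BIC ranking — the test and the information
criteria answer different questions, and both are reported.

Model ranking: ascending AIC, ties by BIC, then by fewer parameters.

## Diagnostics

All diagnostics are computed as data series first and rendered
separately, so they are testable headlessly.

* Empirical CDF: step points (v, fraction ≤ v) per distinct value.
* PP series: one point per *distinct* observed value — x = model CDF at
  the value, y = the Hazen plotting position (i − 0.5)/n of the highest
  tied rank. Collapsing ties is deliberate: per-order-statistic points
  fan each tie block across a full pmf mass on heavily tied discrete
  data, which makes the plot unreadable and uninformative; the
  collapsed series tracks the identity line at the empirical-CDF
  convergence rate when the model is true. For untied data it reduces
  to the usual per-order-statistic construction.
* QQ series: x = model quantile at (i − 0.5)/n (smallest support point
  whose CDF reaches the probability — the discrete-quantile
  convention), y = the order statistic.

## Minimum-effort experiment

The best family is chosen **once on the full census** and held fixed
across subsamples (it is refitted to each subsample's counts, but the
family is not re-selected; a per-subsample re-selection is available as
an argument for sensitivity checks). For each fraction f in
{0.90, 0.85, …, 0.05} and each of 25 replicates:

1. Draw `round_half_up(f × n)` cells (minimum 1) by simple random
   sampling *without* replacement — cells are physical plots.
2. Estimate the total by expansion: T̂ = n × μ̂ × CF, with μ̂ the fitted
   mean of the subsample. Since μ̂ is the sample mean for every family,
   T̂ is the classical expansion estimator, and at f = 1 it reproduces
   the census total exactly.
3. ML interval: log-normal delta method. log T̂ has standard error
   s = SE(μ̂)/μ̂ with SE(μ̂) = √(V̂/n_sampled) and V̂ the fitted family's
   variance at the MLE (the inverse information for the mean). The
   interval T̂·exp(∓z₁₋α/₂·s) is positive and asymmetric with
   high/T̂ = T̂/low. Degenerate inputs: an all-identical sample returns
   a zero-width interval at T̂ (no estimable spread); an all-zero
   sample returns (0, 0) with a warning.
4. SB interval: the subsample is resampled with replacement B times
   (default 10,000) and the (α/2, 1−α/2) percentiles of the re-estimated
   totals taken. Re-estimation is vectorised through the identity
   estimate = n × resample mean × CF, which is exactly what refitting
   any of the three families would return. Percentile (not BCa) is used
   as the plainest reading of a "simple" bootstrap.

No finite-population correction is applied anywhere: the target of
inference is the superpopulation total n × μ, consistent with the
distribution-fitting step. Conditional on one realised wall, the
intervals are therefore somewhat conservative for the realised census
total at high sampling fractions (the boxplot summaries show exactly
this as coverage near 1 at large f).

Randomness: one root seed; each (fraction, replicate) cell gets its own
`numpy` generator seeded by (root, fraction index, replicate), so the
record table is byte-reproducible and independent of execution order.

Summary and recommendation: per fraction and method — mean estimate,
mean/extreme CI bounds, mean width, and coverage of the full-census
total. The recommended method is the one with the smaller mean CI width
at the fraction of interest (default: the fraction nearest 55%, a
useful mid-range effort to inspect in detail). The recommended minimum
fraction is the smallest one whose mean relative CI half-width is
≤ 0.15 and whose coverage is ≥ 0.90 — both thresholds are configuration,
not doctrine: on real data the decision is made by inspecting the
effort plots, and the defaults merely encode "about ±15% precision,
intervals that usually contain the truth".

## Synthetic data

`synthetic` generates the study conditions end to end: 147 cells by
default (a ~1470 m² wall on a 10 m grid), i.i.d. counts from a chosen
family (defaults: Poisson with mean 5 — a moderately dense wall where
every cell is countable), a true CF of 1.5 with 10% relative Gaussian
observer noise, and 35 calibration areas (inside the recommended 30–40
band). Observer error is multiplicative with Gaussian relative noise
and integer rounding, the minimal model consistent with a ratio-based
CF; the rounding makes recovered CFs very slightly biased upward
(Jensen effect of order the noise variance, ~1% here), which is far
below a single calibration study's standard error — the CF-recovery
checks are phrased against that standard error for exactly this reason.

What passing synthetic tests do **not** show about real cliffs: no
spatial autocorrelation between cells, no observer drift between
sessions, no detectability gradient with distance or angle, and no
phenological change between visits. The pipeline's guarantees are
conditional on the i.i.d. count model being adequate, which is exactly
what the χ²/AIC stage is there to check on each real wall.

## Problem sizes used in the checks

The test suite and the acceptance script run at desk scale, chosen to
make the Monte-Carlo bands tight enough to be meaningful while staying
quick: 50 fixtures for the closed-form MLE identities; a 30,001-point
log-spaced grid as the independent NB likelihood oracle (10 fixtures);
100 seeds of n = 2000 for the χ² level; 100 seeds per regime at n = 500
for model selection; 500 replicates of a 200-cell Poisson(6) wall at
50% effort for interval coverage, with the bootstrap at B = 2,000; the
full 18 × 25 default design (B = 2,000) for the width-monotonicity
check; and 200 seeds of 35-pair studies for CF recovery.
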