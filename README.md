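# cliffcensus

Estimating plant population sizes on inaccessible rocky cliffs — and
finding the minimum sampling effort that still gives a reliable estimate.

## The problem

Rupicolous (cliff-dwelling) plants are censused remotely: the wall is
photographed, rectified and overlaid with a square grid (10 m × 10 m
cells), and an observer counts "visual units" — the plant units
distinguishable through a terrestrial telescope — cell by cell. Partial
cells at the image borders are excluded to avoid edge effects. Two
statistical questions follow:

1. **Calibration.** Telescope counts under-resolve the truth. A
   correction factor (CF) is estimated from 30–40 calibration areas
   counted twice, at low (20×) and high (60×) magnification (or against
   true counts where the rock is accessible). The CF is the mean of the
   per-area ratios *high/low* — individuals per visual unit — and
   multiplies every cell count. The ratios are checked for approximate
   normality (Shapiro–Wilk) before the mean is trusted.

2. **Minimum effort.** Full-wall censuses are slow, dangerous and
   weather-limited. If the per-cell counts follow a known count
   distribution, the population total can be estimated from a random
   subset of cells. The toolkit fits Geometric, Poisson and Negative
   Binomial models by maximum likelihood, ranks them by AIC/BIC with a
   χ² goodness-of-fit check, and then re-censuses synthetically:
   random subsamples at fractions 90% down to 5% (step 5%, 25 replicates
   each), expanding each subsample to a total

   *T̂ = n_cells × μ̂ × CF*,

   where μ̂ is the fitted (= sample) mean. Each estimate carries two 95%
   confidence intervals — a log-normal maximum-likelihood (ML) interval
   and a simple percentile bootstrap (SB, 10,000 resamples) — and the
   smallest fraction whose intervals stay tight and reliable is the
   recommended minimum effort.

Intended users: botanists and conservation scientists monitoring
threatened flora in vertical or otherwise extreme terrain.

## Worked example

Simulate a ~1470 m² wall (147 cells, Poisson(5) counts, true CF 1.5
with 10% observer noise), then run the whole workflow:

```bash
$ cliffcensus simulate --seed 7 --out demo
wrote census (147 cells, realised total 739) and 35 calibration pairs to demo

$ cliffcensus cf --input demo/calibration_pairs.csv --out demo_cf
CF = 1.5319 (sd 0.2486, n 35, normality p 0.001)

$ cliffcensus fit --input demo/census.csv --out demo_fit
census total (visual units): 739
           poisson: AIC    636.93  BIC    639.92  chi2    4.80 (df 8, p 0.7791)
 negative_binomial: AIC    638.93  BIC    644.91  chi2    4.80 (df 7, p 0.6848)
         geometric: AIC    798.24  BIC    801.24  chi2  141.41 (df 8, p 0.0000)
best family by AIC: poisson

$ cliffcensus effort --input demo/census.csv --seed 42 --out demo_eff
census total: 739.0
family: poisson; records: 450
recommended CI method at 55%: SB
recommended minimum sampling fraction: 25%
```

Reading the output: the estimated CF (1.53) is within one standard
error of the simulated truth (1.5); integer rounding of the paired
counts makes the ratios slightly lumpy, hence the normality warning.
The Poisson fit wins on AIC and passes the χ² test (p = 0.78); the
Negative Binomial collapses onto it (same likelihood, one parameter
more) and the Geometric is firmly rejected. The effort run (18
fractions × 25 replicates, B = 10,000) finds that censusing 25% of the
cells already keeps the mean relative CI half-width within 15% with
≥ 90% coverage of the full-census total — a quarter of the fieldwork
for a usable estimate. `demo_eff/` contains the per-replicate records
(CSV), the per-fraction summary (JSON), boxplot figures and a manifest
that reproduces the run byte-for-byte.

The same workflow is available as a library; see the module docstrings
in `src/cliffcensus/`.

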