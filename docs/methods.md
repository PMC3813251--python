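# Methods

## Models

**Calibration.** The detector response is modelled as
`area = b·conc + a`, fitted by ordinary *unweighted* least squares (the
classical treatment for a 1–20 µg/mL HPLC-UV range; heteroscedastic weighting
is deliberately not applied by default since replicate CVs in this range are
roughly concentration-independent). `r²` is the plain squared Pearson
correlation (not adjusted). Slope/intercept standard errors use the residual
variance with n−2 degrees of freedom; a two-point fit returns NaN standard
errors rather than refusing (the Arrhenius stage legitimately fits two
temperatures). Back-calculation inverts the line. LOD is defined through the
predicted *net* signal: the smallest concentration with `b·conc ≥ 3·σ_noise`,
i.e. `3·σ_noise/b`, with the baseline noise SD a user input (raw chromatogram
traces are out of scope, so an injected-dilution search is not possible). LOQ
is the lowest calibration level whose replicate CV% is at or below a
threshold (default 1.5%); if no level qualifies the LOQ is returned as a
flagged undefined value, not an exception.

**Kinetics.** A percent-remaining time course `C_t = 100·area(t)/area(0)` is
fitted under one of three rate laws by linearization and OLS:

| order  | linearized response | rate constant | half-life |
|--------|--------------------|---------------|-----------|
| zero   | `C_t`              | `k = −slope`  | `C₀/(2k)` |
| first  | `log₁₀ C_t`        | `k = −slope·ln 10` | `ln 2 / k` |
| second | `1/C_t`            | `k = slope`   | `1/(k·C₀)` |

The base-10 convention matches how degradation plots are traditionally drawn;
the conversion uses the exact `ln 10 = 2.302585…`, not the rounded 2.303, and
half-lives use the exact `ln 2` (see "Reproducing the published tables"
below for the one-cell consequences). Internal time unit is always hours;
minutes appear only at the reporting layer via a per-panel display flag.
Points at or below 1% remaining are excluded from log/reciprocal
linearizations (with a logged count): there the transform amplifies relative
noise without adding kinetic information. A fitted non-negative slope under
first order is reported as `k ≤ 0` with a `degrading=False` flag and an
undefined (NaN) half-life instead of an exception, because "no measurable
degradation" is a scientific result (base stress behaves this way).

**Order screening.** `select_order` fits all three laws and picks the highest
r²; when candidates lie within Δr² = 0.005 of the best, the *lowest* order
wins (parsimony — a nearly-as-linear simpler law should not lose to transform
curvature). The screen needs ≥ 4 points and a decay window of roughly one
half-life or more to discriminate; with shorter windows all three transforms
are near-linear and the tie-break dominates.

**Arrhenius.** `ln k` is regressed on `1/T_K` with `T_K = T_°C + 273.15`
(the 273 vs 273.15 choice is below reporting precision) and
`Ea = −slope·R`, `R = 8.314 J mol⁻¹ K⁻¹`; the intercept is `ln A` with `A`
per hour. The regression is unweighted by default, matching the classical
graphical treatment. The OLS slope SE propagates to an SE on Ea; this is an
extension beyond the traditional plot and is labelled as such in summaries.
Duplicate temperatures are collapsed to the mean of their `ln k` (geometric
mean of k) with a warning. Expressing k per minute instead of per hour
shifts `ln A` by `ln 60` and leaves Ea invariant (tested).

## Synthetic data

The generator emulates the study design of a forced-degradation programme:
six-level calibration series (1, 2, 5, 10, 15, 20 µg/mL; default line slope
39.49, intercept −8.39, the published response of the cetirizine assay),
stress panels of ≥ 2 temperatures with first/zero/second-order decay, and
Gaussian (optionally skewed) peak descriptors for suitability checks.

Noise is **multiplicative Gaussian** on areas and percentages (default
CV = 1%): CV-type dispersion is how replicate precision is reported for such
assays, and the published within-day CVs (≈0.6–1.5%) bracket 1%. The
replicate-to-replicate variance of the original degradation experiments was
not published, so 1% is a stand-in choice, made once. Simulated
percent-remaining values below 0.1% are clamped to 0.1 and counted
(`TimeCourse.n_clamped`) rather than emitted near-zero or negative. The
original sampling time grids were also not published; reconstructions use
grids spanning two half-lives (8–10 points), which keeps every point above
the 1% exclusion floor while giving enough curvature for order
discrimination.

Randomness: one integer seed per call via `numpy.random.default_rng`; stress
panels derive the per-temperature stream as `seed + index` with temperatures
in ascending order, so a fixed seed reproduces every element bit-for-bit and
adding a temperature does not reshuffle the others.

What the simulations do **not** capture: drift and carryover between
injections, heteroscedasticity across the calibration range, peak-shape
degradation, co-eluting degradation products, and non-isothermal oven
excursions. Passing round-trip tests therefore demonstrates correctness of
the estimators under the stated noise model, not robustness of the assay to
real-instrument pathologies.

## Numerical choices

- OLS via `scipy.stats.linregress`, cross-checked in the test suite against
  an independent naive normal-equations oracle at 1e-10 relative tolerance.
- Exact constants throughout (`ln 2`, `ln 10`); rounding only at the
  reporting layer: k to 3 decimals, t½ to 1 decimal, r² to 3 decimals —
  matching the conventional table format.
- Degenerate inputs fail loudly and specifically: zero predictor variance →
  `SingularFitError`; < 3 usable points → `InsufficientDesignError`;
  non-positive reference areas, times out of order, k ≤ 0 into an Arrhenius
  fit → `InvalidInputError`. Non-positive areas inside a series are excluded
  with a logged warning rather than failing the whole series.
- Plate count defaults to the half-height formula `N = 5.54 (t_R/W_h)²`; the
  tangent (4σ) variant is available behind a switch and, for a Gaussian peak,
  agrees with the half-height value to ~0.1% (`16/4² = 1` vs `5.54/2.3548²
  ≈ 0.999`). The published plate count (≈3500 at t_R = 5 min) corresponds to
  σ ≈ 0.0845 min, the generator's default width.
- Peak asymmetry is parameterised as the trailing/leading half-width ratio
  `a`, giving tailing factor `(1 + a)/2` in closed form.

## Reproducing the published tables

The published study reports, per temperature, the linearized equation, r², k
and t½, plus an activation energy per panel. Reconstructing those chains from
the *printed* (rounded) numbers succeeds cell-for-cell with two well-understood
exceptions, which the acceptance tests keep strict and failing rather than
padding with tolerance:

- **50 °C oxidative k:** the printed slope −0.127 gives
  `0.127·ln 10 = 0.2924 → 0.292`, while the printed k is 0.293. The printed
  half-life (141.9 min ⇒ k = 0.2931/h) shows the unrounded slope was
  ≈ −0.1273; the printed slope is too coarse to reproduce the k cell.
- **60 °C oxidative t½:** `ln 2/0.444 = 93.67 min → 93.7`, printed 93.6 —
  exactly what the rounded constant 0.693 yields (`0.693/0.444 = 93.65`).
  This package keeps the exact `ln 2`.

Similarly, the activation energies recomputed from the printed 3-decimal rate
constants are 129.6 kJ/mol (acid; reported 121.8) and 37.5 kJ/mol (peroxide;
reported 36.3). At 70 °C the acid-panel k is printed as 0.005 with only one
significant figure — a ±10% rounding band on that single point alone moves
the recomputed Ea by several kJ/mol, which accounts for the gap. The
reports flag this as a rounding-induced discrepancy instead of silently
matching the published values.

## Problem sizes

Stochastic round-trip checks use 100 seeds × 4 temperatures × 10 time points
at 1% noise (median recovered-k error in that setting is ≈0.4%, far inside
the 3% acceptance band, and first-order is selected in 100/100 seeds); the
OLS oracle comparison uses 1,000 random instances of 3–40 points. These sizes
give stable medians and proportions while keeping the whole suite fast.

## Known limitations

- Single-species kinetics only: no mechanistic modelling of degradation
  products, consecutive/parallel reactions, or pH/ionic-strength effects.
- The published precision/accuracy and suitability tables cannot be
  independently recomputed (raw replicate values were not published); they
  are covered by format-level and property tests only.
- No Eyring or humidity-dependent (ICH Q1A storage condition) treatments.
- Confidence intervals beyond the OLS standard errors (e.g. bootstrap on the
  k estimates) are not implemented.
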