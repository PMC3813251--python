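# stabkin

Stability kinetics of drug degradation from forced-degradation HPLC studies:
calibration and method-validation statistics, percent-remaining time courses,
pseudo-first-order kinetic fitting, and Arrhenius activation-energy
estimation — with a synthetic-data generator that stands in for the
instrument so every stage is testable against known ground truth.

## The problem

Regulatory stability programmes stress a drug substance (acid, base, oxidant,
heat) and quantify the intact drug over time with a validated,
stability-indicating HPLC assay. The worked system here is cetirizine
dihydrochloride, which degrades in 2 M HCl (70–90 °C) and in 0.5% H₂O₂
(50–80 °C) but is essentially stable in base. Analysts need three things from
such data:

1. **A validated calibration** — a linear detector response
   `area = b·conc + a` over 1–20 µg/mL, with slope dispersion, r², LOD
   (signal-to-noise 3), LOQ (replicate CV below 1.5%), precision/accuracy
   tables, and USP system-suitability checks (theoretical plates
   `N = 5.54 (t_R/W_h)²`, tailing factor `T = W₀.₀₅/(2f)`, injection RSDs).
2. **Rate constants and half-lives.** With the stressor in large excess,
   degradation is pseudo-first-order: the percent remaining
   `C_t = 100·area(t)/area(0)` follows
   `log₁₀ C_t = log₁₀ C₀ − k·t/ln 10`, so an OLS fit of `log₁₀ C_t` against
   `t` gives `k = −slope·ln 10` (the classical "2.303" factor) and
   `t½ = ln 2 / k`. Zero- and second-order laws are fitted too and the most
   linear plot wins, with a parsimony tie-break.
3. **Temperature extrapolation.** The Arrhenius law `k = A·e^(−Ea/RT)` makes
   `ln k` linear in `1/T`; OLS over the per-temperature rate constants gives
   the activation energy `Ea = −slope·R` (R = 8.314 J mol⁻¹ K⁻¹) and lets you
   predict `k` and `t½` at storage temperatures.

The package is organised statsmodels-style: `CalibrationModel`,
`KineticModel` and `ArrheniusModel` are built from data and `.fit()` returns
a results object with estimates, standard errors and a `summary()`.

## Worked example

Simulate an acid-stress panel at the four literature rate constants with 1%
multiplicative noise, fit every temperature, and estimate Ea:

```python
import math, numpy as np
from stabkin import KineticTruth, simulate_stress_panel, fit_kinetics
from stabkin.arrhenius import ArrheniusModel
from stabkin.pipeline import render_kinetics_table

truths = {t: KineticTruth(model="first", k=k)
          for t, k in {70: 0.005, 80: 0.014, 85: 0.030, 90: 0.062}.items()}
times = {t: list(np.linspace(0, 2 * math.log(2) / tr.k, 8))
         for t, tr in truths.items()}
panel = simulate_stress_panel(truths, times, noise_cv=0.01, seed=42,
                              condition="2 M HCl")
fits = {tc.temperature_c: fit_kinetics(tc) for tc in panel}
print(render_kinetics_table(fits, "h").to_string(index=False))
print(ArrheniusModel.from_fits(fits).fit().summary())
```

prints

```
 Temperature_C            Equation  r2  k_per_h  t_half_h
          70.0 y = -0.002x + 2.000 1.0    0.005     138.0
          80.0 y = -0.006x + 1.999 1.0    0.014      49.5
          85.0 y = -0.013x + 2.005 1.0    0.030      22.8
          90.0 y = -0.027x + 1.998 1.0    0.062      11.3

Arrhenius fit (n = 4 temperatures)
  slope (K)        -15540.2
  Ea (kJ/mol)      129.2
  SE of Ea (kJ/mol, OLS extension)  10.6
  ln A (A in 1/h)  39.91
  r^2              0.9866
```

Each row is one temperature's linearized plot (`y = log₁₀ percent remaining`
vs hours): the fitted slope converts to the apparent rate constant `k` (1/h)
and half-life `t½ = ln 2/k`; e.g. at 90 °C the drug halves every ~11 h, and at
70 °C every ~138 h. The Arrhenius fit across the four temperatures gives an
activation energy of ≈129 kJ/mol — a strongly temperature-sensitive
degradation, recovered here to within its own OLS standard error despite the
1% injection noise.

The same stages are scriptable from the shell:

```sh
stabkin simulate --noise-cv 0 --out cal.csv && stabkin validate cal.csv
stabkin arrhenius --point 70:0.005 --point 80:0.014 --point 85:0.030 --point 90:0.062
stabkin run --config config.yaml     # full pipeline -> CSV tables + summary.json
```

A complete `run` configuration looks like:

```yaml
seed: 1
output_dir: out
calibration: {levels: [1, 2, 5, 10, 15, 20], days: 6, noise_cv: 0.01}
panels:
  acid:
    condition: 2 M HCl
    half_life_unit: h
    truths: {70: 0.005, 80: 0.014, 85: 0.030, 90: 0.062}
  peroxide:
    condition: 0.5% H2O2
    half_life_unit: min
    truths: {50: 0.293, 60: 0.444, 70: 0.693, 80: 0.942}
```

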