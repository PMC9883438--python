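# cushingsr

Stock–recruitment modelling for a recovering sea-turtle rookery whose
recruitment regime drifts with a multidecadal climate cycle.

Annual counts of nesting females *S* (the stock) and the hatchlings *R* they
produce (the recruits) from a population rebounding after depletion are well
described by the Cushing power law

    R = a · S^b,

where *b* sets the production regime (*b* > 1 accelerating, *b* = 1 linear,
*b* < 1 decelerating hatchlings per nester). This package implements the full
analysis chain around that curve for populations whose exponent is driven by
a basin-scale sea-surface-temperature anomaly cycle:

- **Static fits and local regression** — OLS on the linearization
  ln *R* = ln *a* + *b* ln *S*, refit in sliding 9-year windows keyed to each
  window's right endpoint, to track drift in *b*.
- **Climate harmonic** — a fixed-period (default 26-year) sinusoid fit to an
  annual anomaly index by sin/cos least squares, evaluated analytically at
  any year, lagged, and scanned for the lag maximizing r² against a target
  series.
- **Extended Cushing regression** — the stochastic model

      R_t = ( √(a · S_t^(γ₀ + γ₁·T_t)) + (σ/2)·ε_t )²,   ε_t ~ N(0, 1) i.i.d.,

  where T_t is the lagged cycle value. The exponent b_t = γ₀ + γ₁·T_t is
  linear in the climate covariate; the squared-root-perturbation noise law
  gives a positively skewed response whose variance grows with its median,
  and σ → 0 collapses the model to the deterministic Cushing curve. Fitting
  is maximum likelihood on the √R scale (nonlinear least squares with σ
  profiled out), with Wald standard errors, t-based 95% intervals, exact
  response quantiles for prediction bands, the recruitment rate
  RR = a·b(T)·S^(b(T)−1), and Shapiro–Wilk / Ljung–Box residual diagnostics.
- **Synthetic data** — a seeded generator reproducing the study conditions
  (37 years, nesters recovering from ~6 to ~2,700, a 26-year cycle acting at
  a 3-year lag) for parameter-recovery and calibration experiments.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```
python analysis/01_simulate_rookery.py --seed 1
python analysis/02_local_exponent_drift.py
python analysis/03_lag_scan.py --seed 1
python analysis/04_fit_extended.py
python analysis/05_parameter_recovery.py --seed 1
```

With seed 1 the simulated rookery spans 6 → 2,628 nesters over 1984–2020;
the 9-year window produces 29 local exponent estimates keyed 1992–2020, and
the extended-model fit prints

```
        estimate  std_err   ci_lo   ci_hi  t_value   p_value
a          219.5    40.14   151.4   318.3    5.468 4.237e-06
gamma0     1.024   0.0294  0.9641   1.084    34.82  3.52e-28
gamma1   -0.6155   0.0388 -0.6944 -0.5367   -15.86 2.781e-17
sigma = 38.51
observed vs fitted hatchlings: r2 = 0.998
residuals: Shapiro-Wilk p = 0.115, Ljung-Box(lag 7) p = 0.477
```

i.e. a single noisy 37-year realization already pins γ₁ well away from zero
(a genuine climate effect on the exponent; the generating values were
a = 264.299, γ₀ = 0.999, γ₁ = −0.615, σ = 50.65). Across 500 replicates
(driver 05) the median estimates are a ≈ 261.6, γ₀ ≈ 0.9992, γ₁ ≈ −0.619,
σ ≈ 49.9 with 95%-interval coverage of 0.95–0.96 per parameter.

Driver 03 also documents a methodological caveat: under smooth exponential
stock growth the windowed OLS exponent series is dominated by an amplified
*derivative* of the cycle, so its lag scan does not point back at the
generating lag (see `docs/methods.md`).

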