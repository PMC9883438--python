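# Methods

## The model

The package analyses annual stock–recruitment (SR) pairs for a recovering
rookery: *S_t* nesting females produce *R_t* hatchlings in year *t*. For a
population rebuilding from very low numbers, recruitment does not plateau,
which motivates the Cushing power law R = a·S^b. The parameter *a* is a
units conversion factor with no biological content; *b* is the shape of the
production regime.

The dynamic model lets the exponent track a climate covariate. With *T_t*
the value of a fixed-period temperature-anomaly cycle applied at a lag,

    b_t = γ0 + γ1·T_t
    R_t = ( sqrt(a·S_t^{b_t}) + (σ/2)·ε_t )²,   ε_t i.i.d. N(0, 1).

Properties used throughout:

- **Embedding.** γ1 = 0 reduces the median response to the static curve for
  every T; σ = 0 reproduces the deterministic relationship exactly.
- **Median and rate.** med(R) = a·S^{b(T)} independently of σ; the
  recruitment rate (hatchlings per additional nester) is
  RR = a·b(T)·S^{b(T)−1}, the derivative of the median in S.
- **Noise law.** sqrt(R) deviates from sqrt(med R) by a N(0, σ/2) amount, so
  R is positively skewed with E[R] = μ² + σ²/4 and
  Var[R] = μ²σ² + σ⁴/8 where μ = sqrt(a·S^{b(T)}): variance grows with the
  median, matching the heteroscedastic, right-skewed look of hatchling
  counts. The exact CDF is P(R ≤ r) = Φ((√r − μ)/(σ/2)) − Φ((−√r − μ)/(σ/2)).

### Estimation

Maximum likelihood for the working model sqrt(R_t) ~ N(μ_t, σ/2) is
nonlinear least squares on the sqrt scale. `fit_extended` optimizes
(log a, γ0, γ1) with `scipy.optimize.least_squares` (LM, tolerances 1e−13),
starting from the linearized whole-series Cushing fit with γ1 = 0; the log
parameterization of *a* enforces positivity. σ is profiled from the
residual sum of squares: the default estimator is 2·sqrt(RSS/(n − 3)) (the
residual standard error with three mean parameters, the convention of
standard nonlinear-least-squares software); 2·sqrt(RSS/n) — the pure ML
variant maximizing the reported log-likelihood — is available with
`sigma_estimator="ml"`. The paper trail for the headline σ of such fits
rarely states the denominator; both are one call apart.

Uncertainty is Wald: covariance (RSS/(n−3))·(JᵀJ)⁻¹ from the Jacobian at
the optimum, intervals estimate ± t₀.₉₇₅,ₙ₋₃·SE, with the interval for *a*
formed on the log scale and exponentiated (which is why it is asymmetric,
as such published tables are), SE(a) by the delta method, and two-sided t
p-values with n − 3 degrees of freedom. These are the usual nls outputs;
profile-likelihood intervals are out of scope.

The reported log-likelihood is the Gaussian log-likelihood of sqrt(R),
ignoring the folding of the square at negative μ + (σ/2)ε; the folded term
is numerically zero whenever μ/(σ/2) is appreciable, which holds everywhere
the model is sensible (it is ≥ 1.7 even at S = 6 under the default truth).

### Prediction bands

Quantiles of R invert the exact two-sided CDF by monotone root-finding
(Brent on sqrt(R), xtol 1e−12). When μ/(σ/2) > 8 the folded term is below
machine precision and the closed form (μ + (σ/2)·z_q)² is used — it is then
identical to the root. The 0.5 quantile coincides with the median response
in that regime and differs only at extreme noise-to-signal ratios, where
the exact inverse is still valid. Degenerate σ = 0 returns
lower = median = upper.

### Diagnostics

Standardized sqrt-scale residuals are tested for normality (Shapiro–Wilk)
and serial independence (Ljung–Box at lag min(10, n/5); lag 7 at n = 37),
with pass flags at α = 0.05. At least 8 residuals are required.

## Climate harmonic and lag scanning

The covariate is a single fixed-period sinusoid
offset + A·sin(2π(t − φ)/P), default P = 26 years, fit to an annual anomaly
index by OLS on the sin/cos pair plus intercept (A = hypot of the two
coefficients, φ reported modulo P). Monthly index input is reduced to
annual arithmetic means first. A full spectral decomposition of the index
is deliberately not attempted: one fixed-period component is the covariate
of interest, and a user-supplied precomputed cycle series can bypass
extraction entirely. Because the fitted cycle is analytic, lagging
(T_t = cycle(t − lag)) never truncates the abundance series.

`lag_scan` computes Pearson r between a target series and the cycle at lags
0..max_lag, selecting the lag with maximal r² (ties toward the smaller
lag). The scan is invariant to affine rescaling of the target, so the
amplitude normalization of the cycle does not affect lag selection; γ1, by
contrast, is only interpretable jointly with the cycle scaling used in the
fit, which the cycle series records.

## Windowed local regression, and a confound its users should know

`local_regression` refits the linearized Cushing model in sliding windows
(default 9 years, uniform OLS, no robustness weighting) over a consecutive
series, keying each fit to the window's right endpoint: 37 years and a
9-year window give exactly 29 estimates, keyed like 1992–2020.

Interpreting that series as "b at the key year" carries two systematic
effects under this package's own generative model:

1. **Moving-average delay.** A trailing window centred (w−1)/2 = 4 years
   before its key smooths and delays the exponent signal; the pipeline
   helper re-keys estimates to window midpoints before lag scanning.
2. **Amplified-derivative confound.** Within a window, ln S grows nearly
   linearly in time while b_t varies, so the OLS slope estimates the local
   mean of b_t *plus* approximately (mean ln S / growth rate)·db/dt. At the
   study scale (ln S up to ~7.9, growth ≈ 0.17 yr⁻¹) the derivative term is
   amplified ~25–40×, against an exponent signal of amplitude
   |γ1|·A ≈ 0.12. The windowed series is therefore phase-shifted about a
   quarter period from the cycle, and a lag scan on it does **not** recover
   the lag generating the data: the measured recovery rate across seeded
   replicates is 0 even with σ = 0. `analysis/03_lag_scan.py` and
   `pipeline.lag_recovery_rate` measure this honestly; lag scanning is
   validated on series carrying the lag directly. The confound vanishes
   when b is piecewise constant (regime windows recover their regime
   exactly) and would be milder for stock trajectories that are not
   log-linear in time within windows.

## Synthetic generator

`SyntheticConfig` defaults encode the study conditions: 37 annual
observations starting 1984; nesters growing exponentially from S0 = 6 at
rate ln(2728/6)/36 ≈ 0.170 yr⁻¹ (reaching ~2,728, the observed peak) with
lognormal year-to-year noise of sd 0.2 on the log scale (the scale of the
reported nester-count uncertainty benchmark); a 26-year cycle of amplitude
0.2 anomaly units (the magnitude of the multidecadal SST component) with
phase 1995.5 so the lag-3 covariate peaks in 2005 and bottoms near 2017;
generating parameters a = 264.299, γ0 = 0.999, γ1 = −0.615, σ = 50.65, the
scale of the published headline fit. Hatchlings are drawn exactly from the
extended-model noise law, rounded to integer counts; draws rounding to zero
are redrawn (vanishingly rare at these parameter values) and counted in the
truth record. Everything is deterministic under the mandatory seed, file
outputs byte-identical. `generate_climate_index` adds white noise (sd 0.15
anomaly units) to the cycle over 1900–2010 to emulate a raw long-span
index for harmonic re-extraction.

What the generator does **not** emulate: observation error on S distinct
from process variation, demographic age structure and remigration
intervals, non-sinusoidal climate variability, monitoring-protocol changes,
or any dependence between S_t and past R. Passing tests therefore
demonstrate internal consistency of the estimators under the model's own
assumptions at the study's scale — not that real rookery data satisfy those
assumptions.

## Problem sizes and tolerances

Monte-Carlo studies use 500 replicates at n = 37 for parameter recovery
(median bias and interval coverage), 200 replicates for lag-recovery rates,
10⁵ draws for prediction-band coverage and 10⁶ draws for the moment checks;
these sizes give Monte-Carlo standard errors comfortably below the effects
being measured while keeping any single run in seconds. Brute-force grid
oracles (ln-scale SSE for the static fit, a 4-D likelihood grid at n = 6,
dense amplitude/phase/offset grids for the harmonic) back the optimizers in
the test suite. Degenerate inputs are refused explicitly: all-equal S is a
singular design; all-equal T makes γ1 unidentifiable and the fit instructs
the caller to fix γ1 = 0; constant targets make correlations undefined.

## Limitations

- Estimates and derived quantities (median response, RR, bands) are only
  meaningful within the observed ranges of S and T; nothing here supports
  extrapolation beyond them.
- Wald intervals at n = 37 are approximate; coverage measured by simulation
  at the default conditions is 0.95–0.96 per parameter, but can degrade for
  smaller n or weaker climate signals.
- The windowed-exponent lag scan is exploratory at best under trending
  stock (see the confound above); inference about the climate link should
  rest on the extended model's γ1, not on the windowed correlation.
- The reproduction of the original study's numerical table requires its
  supplementary abundance data and an anomaly index, which are not
  redistributed here; with those files in `data/`, the final acceptance
  test runs the full real-data pipeline.
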