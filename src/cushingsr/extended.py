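"""The extended Cushing model: a climate-driven exponent with sqrt-scale noise.

The response model is

    R_t = ( sqrt(a * S_t**(gamma0 + gamma1*T_t)) + (sigma/2) * eps_t )**2,

with eps_t i.i.d. standard normal.  Squaring a perturbed square root gives a
positively skewed response whose variance grows with its median — the two
features annual hatchling counts display — while sigma -> 0 collapses the
model to the deterministic Cushing curve.  The median response is
``a * S**b(T)`` with ``b(T) = gamma0 + gamma1*T`` and the recruitment rate
(hatchlings per additional nester) is its derivative in S.

Estimation is nonlinear least squares on the sqrt(R) scale, i.e. maximum
likelihood for sqrt(R) ~ Normal(sqrt(a*S**b(T)), sigma/2) with sigma profiled
out, with Wald uncertainty from the Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .climate import CycleSeries
from .cushing import CushingParams
from .series import AbundanceSeries, ValidationError

__all__ = [
    "ExtendedParams",
    "ExtendedFit",
    "PredictionBand",
    "DiagnosticsReport",
    "b_of_T",
    "median_response",
    "recruitment_rate",
    "simulate_response",
    "response_cdf",
    "response_quantile",
    "fit_extended",
    "prediction_band",
    "diagnostics",
    "residual_diagnostics",
]

_PARAM_NAMES = ("a", "gamma0", "gamma1")


@dataclass(frozen=True)
class ExtendedParams:
    """Parameters (a, gamma0, gamma1, sigma) of the extended model.

    ``sigma`` is scaled so that sqrt(R) has standard deviation sigma/2 around
    sqrt of the median response.
    """

    a: float
    gamma0: float
    gamma1: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"a must be positive, got {self.a}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        for name in ("gamma0", "gamma1"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def static(self, T: float = 0.0) -> CushingParams:
        """The Cushing curve in force at covariate value T."""
        return CushingParams(a=self.a, b=b_of_T(self, T))


def b_of_T(params: ExtendedParams, T):
    """Exponent in force at anomaly T: gamma0 + gamma1 * T."""
    t = np.asarray(T, dtype=float)
    out = params.gamma0 + params.gamma1 * t
    return float(out) if np.isscalar(T) else out


def _check_S(S) -> np.ndarray:
    s = np.asarray(S, dtype=float)
    if np.any(s <= 0):
        raise ValueError("S must be strictly positive")
    return s


def median_response(params: ExtendedParams, S, T):
    """Median hatchlings a * S**b(T); independent of sigma."""
    s = _check_S(S)
    out = params.a * s ** b_of_T(params, np.asarray(T, dtype=float))
    return float(out) if np.isscalar(S) and np.isscalar(T) else out


def recruitment_rate(params: ExtendedParams, S, T):
    """Hatchlings per additional nester: d median / dS = a*b(T)*S**(b(T)-1)."""
    s = _check_S(S)
    b = b_of_T(params, np.asarray(T, dtype=float))
    out = params.a * b * s ** (b - 1.0)
    return float(out) if np.isscalar(S) and np.isscalar(T) else out


def simulate_response(params: ExtendedParams, S, T, rng, size=None):
    """Draw hatchling counts from the model's response distribution.

    ``rng`` is an integer seed or a ``numpy.random.Generator``.  With
    sigma = 0 the draw equals the median response exactly.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s = _check_S(S)
    if params.sigma == 0 and size is None:
        # degenerate noise law: the draw IS the median, bit for bit
        return median_response(params, S, T)
    mu = np.sqrt(params.a * s ** b_of_T(params, np.asarray(T, dtype=float)))
    shape = np.broadcast(mu).shape if size is None else size
    eps = gen.standard_normal(shape)
    out = (mu + 0.5 * params.sigma * eps) ** 2
    if size is None and np.isscalar(S) and np.isscalar(T):
        return float(out)
    return out


def response_cdf(r, mu: float, s: float):
    """P(R <= r) for R = (mu + s*eta)**2, eta standard normal, s = sigma/2."""
    rr = np.asarray(r, dtype=float)
    if s == 0:
        out = (rr >= mu * mu).astype(float)
    else:
        x = np.sqrt(np.maximum(rr, 0.0))
        out = stats.norm.cdf((x - mu) / s) - stats.norm.cdf((-x - mu) / s)
    return float(out) if np.isscalar(r) else out


def response_quantile(level: float, mu: float, s: float) -> float:
    """Quantile of R = (mu + s*eta)**2 by monotone root-finding on sqrt(R).

    When mu/s > 8 the folded term is numerically zero and the shortcut
    (mu + s*z_level)**2 is used; it is then identical to the exact root.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("quantile level must lie strictly inside (0, 1)")
    if s == 0:
        return mu * mu
    if mu / s > 8.0:
        return float((mu + s * stats.norm.ppf(level)) ** 2)

    def g(x: float) -> float:
        return (
            stats.norm.cdf((x - mu) / s) - stats.norm.cdf((-x - mu) / s) - level
        )

    hi = max(mu, 0.0) + 10.0 * s
    while g(hi) < 0.0:
        hi *= 2.0
    x = optimize.brentq(g, 0.0, hi, xtol=1e-12, rtol=8.9e-16)
    return float(x * x)


@dataclass(frozen=True)
class ExtendedFit:
    """MLE result: point estimates with Wald uncertainty and residuals.

    ``se``, ``ci95``, ``tvalue`` and ``pvalue`` are keyed by parameter name
    (a, gamma0, gamma1).  ``residuals`` are standardized sqrt-scale residuals
    (sqrt(R) - fitted sqrt median) / (sigma_hat/2).
    """

    params: ExtendedParams
    se: dict = field(repr=False)
    ci95: dict = field(repr=False)
    tvalue: dict = field(repr=False)
    pvalue: dict = field(repr=False)
    loglik: float
    residuals: np.ndarray = field(repr=False)
    n: int
    dof: int

    def summary(self) -> pd.DataFrame:
        """Parameter table in the usual nonlinear-regression layout."""
        est = {"a": self.params.a, "gamma0": self.params.gamma0, "gamma1": self.params.gamma1}
        return pd.DataFrame(
            {
                "estimate": [est[k] for k in _PARAM_NAMES],
                "std_err": [self.se[k] for k in _PARAM_NAMES],
                "ci_lo": [self.ci95[k][0] for k in _PARAM_NAMES],
                "ci_hi": [self.ci95[k][1] for k in _PARAM_NAMES],
                "t_value": [self.tvalue[k] for k in _PARAM_NAMES],
                "p_value": [self.pvalue[k] for k in _PARAM_NAMES],
            },
            index=list(_PARAM_NAMES),
        )


def _sqrt_mean(theta: np.ndarray, ln_s: np.ndarray, T: np.ndarray) -> np.ndarray:
    log_a, g0, g1 = theta
    return np.exp(0.5 * (log_a + (g0 + g1 * T) * ln_s))


def fit_extended(
    series: AbundanceSeries,
    cycle: CycleSeries,
    *,
    sigma_estimator: str = "dof",
    fix_gamma1: float | None = None,
) -> ExtendedFit:
    """Fit (a, gamma0, gamma1, sigma) by sqrt-scale nonlinear least squares.

    ``a`` is parameterized internally on the log scale to stay positive; the
    start point comes from the linearized whole-series Cushing fit with
    gamma1 = 0.  ``sigma_estimator``: "dof" gives 2*sqrt(RSS/(n-3)) (the
    residual standard error with 3 mean parameters), "ml" gives
    2*sqrt(RSS/n).  If every T is identical gamma1 is unidentifiable: pass
    ``fix_gamma1=0`` to fit the static model instead.
    """
    if not np.array_equal(series.years, np.asarray(cycle.years, dtype=int)):
        raise ValidationError("abundance and cycle series must cover identical years")
    n = len(series)
    if n < 5:
        raise ValidationError("need at least 5 years to fit the extended model")
    if sigma_estimator not in ("dof", "ml"):
        raise ValueError("sigma_estimator must be 'dof' or 'ml'")
    T = np.asarray(cycle.T, dtype=float)
    if fix_gamma1 is None and np.ptp(T) == 0:
        raise ValidationError(
            "all T values identical: gamma1 is unidentifiable; "
            "pass fix_gamma1=0 to fit the static model"
        )
    ln_s = np.log(series.S)
    sqrt_r = np.sqrt(series.R)

    # start at the linearized static fit
    from .cushing import fit_cushing

    static = fit_cushing(series)
    x0 = np.array([np.log(static.params.a), static.params.b, 0.0])

    if fix_gamma1 is not None:

        def resid(th2: np.ndarray) -> np.ndarray:
            return sqrt_r - _sqrt_mean(np.append(th2, fix_gamma1), ln_s, T)

        sol = optimize.least_squares(resid, x0[:2], method="lm", xtol=1e-13, ftol=1e-13)
        theta = np.append(sol.x, fix_gamma1)
        free = 2
    else:

        def resid(th: np.ndarray) -> np.ndarray:
            return sqrt_r - _sqrt_mean(th, ln_s, T)

        sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-13, ftol=1e-13)
        theta = sol.x
        free = 3
    if not sol.success:
        raise RuntimeError(f"extended-model fit did not converge: {sol}")

    res = sqrt_r - _sqrt_mean(theta, ln_s, T)
    rss = float(res @ res)
    dof = n - free
    s_hat = np.sqrt(rss / (dof if sigma_estimator == "dof" else n))
    sigma = 2.0 * float(s_hat)
    params = ExtendedParams(
        a=float(np.exp(theta[0])), gamma0=float(theta[1]), gamma1=float(theta[2]),
        sigma=sigma,
    )

    # Wald covariance of (log a, gamma0, gamma1) from the Jacobian at the optimum
    J = sol.jac  # d resid / d theta
    cov = float(rss / dof) * np.linalg.inv(J.T @ J)
    se_theta = np.sqrt(np.diag(cov))
    tq = stats.t.ppf(0.975, dof)

    se: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    tv: dict[str, float] = {}
    pv: dict[str, float] = {}
    if fix_gamma1 is None:
        se_loga, se_g0, se_g1 = (float(v) for v in se_theta)
    else:
        se_loga, se_g0 = (float(v) for v in se_theta)
        se_g1 = np.nan
    # a: delta-method SE; interval built on the log scale and exponentiated
    se["a"] = params.a * se_loga
    ci["a"] = (
        float(np.exp(theta[0] - tq * se_loga)),
        float(np.exp(theta[0] + tq * se_loga)),
    )
    se["gamma0"] = se_g0
    ci["gamma0"] = (params.gamma0 - tq * se_g0, params.gamma0 + tq * se_g0)
    se["gamma1"] = se_g1
    ci["gamma1"] = (
        (params.gamma1 - tq * se_g1, params.gamma1 + tq * se_g1)
        if np.isfinite(se_g1)
        else (np.nan, np.nan)
    )
    for name, est in zip(_PARAM_NAMES, (params.a, params.gamma0, params.gamma1)):
        t_val = est / se[name] if np.isfinite(se[name]) and se[name] > 0 else np.nan
        tv[name] = float(t_val)
        pv[name] = float(2.0 * stats.t.sf(abs(t_val), dof)) if np.isfinite(t_val) else np.nan

    std_res = res / s_hat if s_hat > 0 else res
    loglik = float(np.sum(stats.norm.logpdf(sqrt_r, _sqrt_mean(theta, ln_s, T), s_hat)))
    return ExtendedFit(
        params=params, se=se, ci95=ci, tvalue=tv, pvalue=pv,
        loglik=loglik, residuals=std_res, n=n, dof=dof,
    )


@dataclass(frozen=True)
class PredictionBand:
    """Per-year median and outer quantiles of the response distribution."""

    frame: pd.DataFrame  # columns: year, S, T, median, lower, upper
    levels: tuple[float, float]


def prediction_band(
    params: ExtendedParams,
    years,
    S,
    T,
    levels: tuple[float, float] = (0.025, 0.975),
) -> PredictionBand:
    """Quantile band of R per year under the exact response distribution.

    The lower/upper levels default to a central 95% prediction interval; the
    median row is the 0.5 quantile, which coincides with the median response
    whenever the signal-to-noise ratio is appreciable.
    """
    lo, hi = levels
    for lv in (lo, hi):
        if not (0.0 < lv < 1.0):
            raise ValueError("prediction levels must lie strictly inside (0, 1)")
    if not lo < hi:
        raise ValueError("levels must be (lower, upper) with lower < upper")
    yrs = np.asarray(years, dtype=int)
    s = _check_S(S)
    t = np.asarray(T, dtype=float)
    mu = np.sqrt(params.a * s ** b_of_T(params, t))
    half_sigma = 0.5 * params.sigma
    med = np.array([response_quantile(0.5, m, half_sigma) for m in mu]) if half_sigma else mu**2
    low = np.array([response_quantile(lo, m, half_sigma) for m in mu]) if half_sigma else mu**2
    upp = np.array([response_quantile(hi, m, half_sigma) for m in mu]) if half_sigma else mu**2
    frame = pd.DataFrame(
        {"year": yrs, "S": s, "T": t, "median": med, "lower": low, "upper": upp}
    )
    return PredictionBand(frame=frame, levels=(float(lo), float(hi)))


@dataclass(frozen=True)
class DiagnosticsReport:
    """Normality and serial-independence checks on standardized residuals."""

    normality: tuple[float, float]  # (Shapiro-Wilk W, p)
    independence: tuple[float, float]  # (Ljung-Box Q at chosen lag, p)
    lb_lag: int
    normal_ok: bool
    independent_ok: bool


def residual_diagnostics(residuals: np.ndarray, alpha: float = 0.05) -> DiagnosticsReport:
    """Shapiro-Wilk and Ljung-Box (lag min(10, n//5)) on a residual vector."""
    res = np.asarray(residuals, dtype=float)
    n = res.size
    if n < 8:
        raise ValidationError("need at least 8 residuals for diagnostics")
    w, p_norm = stats.shapiro(res)
    lag = int(min(10, n // 5))
    from statsmodels.stats.diagnostic import acorr_ljungbox

    lb = acorr_ljungbox(res, lags=[lag])
    q = float(lb["lb_stat"].iloc[0])
    p_lb = float(lb["lb_pvalue"].iloc[0])
    return DiagnosticsReport(
        normality=(float(w), float(p_norm)),
        independence=(q, p_lb),
        lb_lag=lag,
        normal_ok=bool(p_norm > alpha),
        independent_ok=bool(p_lb > alpha),
    )


def diagnostics(fit: ExtendedFit, alpha: float = 0.05) -> DiagnosticsReport:
    """Diagnostics on a fit's standardized sqrt-scale residuals."""
    return residual_diagnostics(fit.residuals, alpha=alpha)
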