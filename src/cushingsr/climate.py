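"""Fixed-period harmonic extraction from a climate index, lagging, lag scans.

A single sinusoid of fixed period (default 26 years, the multidecadal SST
anomaly component used as covariate) is fit by least squares via the linear
sin/cos parameterization.  The fitted cycle is analytic, so it can be
evaluated, and lagged, at any calendar year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import ClimateIndexSeries, ValidationError

__all__ = [
    "HarmonicCycle",
    "CycleSeries",
    "LagScanResult",
    "extract_harmonic",
    "evaluate_cycle",
    "lag_scan",
]


@dataclass(frozen=True)
class HarmonicCycle:
    """A sinusoid ``offset + amplitude * sin(2*pi*(t - phase)/period)``.

    ``phase`` is in years, reported modulo the period; ``amplitude`` and
    ``offset`` are in the index's anomaly units.
    """

    period: float = 26.0
    amplitude: float = 1.0
    phase: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.period > 0):
            raise ValueError("period must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def value(self, years):
        """Evaluate the sinusoid at (possibly fractional) calendar years."""
        t = np.asarray(years, dtype=float)
        out = self.offset + self.amplitude * np.sin(
            2.0 * np.pi * (t - self.phase) / self.period
        )
        return float(out) if np.isscalar(years) else out


@dataclass(frozen=True)
class CycleSeries:
    """The climate covariate T_t: the (lagged) cycle sampled at given years."""

    years: np.ndarray
    T: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "T": self.T})


@dataclass(frozen=True)
class LagScanResult:
    """Per-lag Pearson correlations of a target series with the lagged cycle."""

    table: pd.DataFrame  # columns: lag, r, r2
    best_lag: int

    @property
    def best_r(self) -> float:
        row = self.table.loc[self.table["lag"] == self.best_lag]
        return float(row["r"].iloc[0])

    @property
    def best_r2(self) -> float:
        row = self.table.loc[self.table["lag"] == self.best_lag]
        return float(row["r2"].iloc[0])


def extract_harmonic(index: ClimateIndexSeries, period: float = 26.0) -> HarmonicCycle:
    """Least-squares sinusoid of fixed ``period`` through an annual index.

    Equivalent to OLS on the regressors sin(2*pi*t/period), cos(2*pi*t/period)
    plus an intercept, with amplitude = hypot of the two coefficients.
    """
    if len(index) < 4:
        raise ValidationError("need at least 4 index points to fit a harmonic")
    t = index.years.astype(float)
    y = index.values
    if np.ptp(y) == 0:
        warnings.warn("climate index has zero variance; amplitude set to 0")
        return HarmonicCycle(period=period, amplitude=0.0, phase=0.0, offset=float(y[0]))
    omega = 2.0 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.sin(omega * t), np.cos(omega * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    offset, c_sin, c_cos = (float(c) for c in coef)
    amplitude = float(np.hypot(c_sin, c_cos))
    # c_sin*sin(wt) + c_cos*cos(wt) = A*sin(w(t - phase)) with
    # c_sin = A*cos(w*phase), c_cos = -A*sin(w*phase)
    phase = float(np.arctan2(-c_cos, c_sin) / omega % period) if amplitude > 0 else 0.0
    return HarmonicCycle(period=period, amplitude=amplitude, phase=phase, offset=offset)


def evaluate_cycle(cycle: HarmonicCycle, years, lag: int = 0) -> CycleSeries:
    """Covariate series T_t = cycle(t - lag): the cycle looks back ``lag`` years."""
    if int(lag) != lag or lag < 0:
        raise ValueError("lag must be a non-negative integer")
    yrs = np.asarray(years, dtype=int)
    return CycleSeries(years=yrs, T=cycle.value(yrs - int(lag)))


def lag_scan(years, values, cycle: HarmonicCycle, max_lag: int) -> LagScanResult:
    """Pearson r between a target series and the cycle lagged 0..max_lag.

    ``best_lag`` maximizes r**2; ties break toward the smallest lag.  The
    cycle is analytic, so every lag uses the full overlap of target years.
    """
    yrs = np.asarray(years, dtype=float)
    vals = np.asarray(values, dtype=float)
    if yrs.size != vals.size:
        raise ValueError("years and values differ in length")
    if yrs.size < 3:
        raise ValidationError("need at least 3 target points for a lag scan")
    if not (0 <= max_lag < yrs.size - 2):
        raise ValueError("require 0 <= max_lag < len(target) - 2")
    if np.ptp(vals) == 0:
        raise ValidationError("constant target: correlation undefined")
    rows = []
    for lag in range(int(max_lag) + 1):
        cyc = cycle.value(yrs - lag)
        r = float(np.corrcoef(vals, cyc)[0, 1])
        rows.append((lag, r, r * r))
    table = pd.DataFrame(rows, columns=["lag", "r", "r2"])
    best_lag = int(table.loc[table["r2"].idxmax(), "lag"])  # idxmax: first of ties
    return LagScanResult(table=table, best_lag=best_lag)
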