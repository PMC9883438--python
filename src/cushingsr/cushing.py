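"""Static Cushing stock-recruitment model and its windowed local regression.

The Cushing curve ``R = a * S**b`` describes recruitment that keeps growing
with stock size; the exponent ``b`` sets the regime (b > 1 accelerating,
b = 1 linear, b < 1 decelerating hatchling production per nester).  Because
``ln R = ln a + b ln S`` the model is fit by ordinary least squares on log
scale, both globally and inside a sliding window whose estimate is assigned
to the window's right endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import AbundanceSeries, ValidationError

__all__ = [
    "CushingParams",
    "CushingFit",
    "LocalFitSeries",
    "cushing_median",
    "fit_cushing",
    "local_regression",
]


@dataclass(frozen=True)
class CushingParams:
    """Power-law parameters: conversion factor ``a`` and shape exponent ``b``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"a must be positive, got {self.a}")
        if not np.isfinite(self.b):
            raise ValueError(f"b must be finite, got {self.b}")


@dataclass(frozen=True)
class CushingFit:
    """An OLS fit of the linearized model over a span of years.

    ``r2`` is the squared Pearson correlation of ln R on ln S;
    ``ln_residual_sd`` the residual standard error on the ln scale.
    """

    params: CushingParams
    window: tuple[int, int]
    n: int
    r2: float
    ln_residual_sd: float


def cushing_median(S, params: CushingParams):
    """Expected (median) hatchlings ``a * S**b`` for nester count ``S > 0``."""
    s = np.asarray(S, dtype=float)
    if np.any(s <= 0):
        raise ValueError("S must be strictly positive")
    out = params.a * s ** params.b
    return float(out) if np.isscalar(S) else out


def _fit_loglog(years: np.ndarray, S: np.ndarray, R: np.ndarray) -> CushingFit:
    n = years.size
    if n < 2:
        raise ValidationError("need at least 2 points to fit the Cushing model")
    ln_s = np.log(S)
    ln_r = np.log(R)
    if np.ptp(ln_s) == 0:
        raise ValidationError("all S identical: singular design, b not identifiable")
    res = stats.linregress(ln_s, ln_r)
    b = float(res.slope)
    a = float(np.exp(res.intercept))
    fitted = res.intercept + b * ln_s
    rss = float(np.sum((ln_r - fitted) ** 2))
    sd = float(np.sqrt(rss / (n - 2))) if n > 2 else 0.0
    r2 = float(res.rvalue**2)
    return CushingFit(
        params=CushingParams(a=a, b=b),
        window=(int(years[0]), int(years[-1])),
        n=int(n),
        r2=r2,
        ln_residual_sd=sd,
    )


def fit_cushing(series: AbundanceSeries) -> CushingFit:
    """OLS fit of ln R on ln S over the whole series."""
    return _fit_loglog(series.years, series.S, series.R)


class LocalFitSeries:
    """Window fits keyed to each window's right-endpoint year."""

    def __init__(self, entries: dict[int, CushingFit]) -> None:
        self.entries = entries
        self.years = np.array(sorted(entries), dtype=int)
        self.a = np.array([entries[y].params.a for y in self.years])
        self.b = np.array([entries[y].params.b for y in self.years])
        self.r2 = np.array([entries[y].r2 for y in self.years])

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, year: int) -> CushingFit:
        return self.entries[int(year)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "a": self.a,
                "b": self.b,
                "r2": self.r2,
                "n": [self.entries[y].n for y in self.years],
            }
        )


def local_regression(series: AbundanceSeries, window: int = 9) -> LocalFitSeries:
    """Slide a ``window``-year span over a consecutive series, fitting each.

    The estimate from years ``[t-window+1, t]`` is assigned to year ``t``, so
    an n-year series yields ``n - window + 1`` entries keyed to consecutive
    right-endpoint years.
    """
    if window < 2:
        raise ValueError("window must be at least 2 years")
    series.require_consecutive()
    n = len(series)
    if n < window:
        raise ValidationError(f"series of {n} years is shorter than window {window}")
    entries: dict[int, CushingFit] = {}
    for i in range(n - window + 1):
        sl = slice(i, i + window)
        fit = _fit_loglog(series.years[sl], series.S[sl], series.R[sl])
        entries[int(series.years[i + window - 1])] = fit
    return LocalFitSeries(entries)
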