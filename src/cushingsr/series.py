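"""Annual abundance and climate-index series: containers, validation, CSV I/O.

The abundance series pairs, for each calendar year, the number of nesting
females ``S`` (the stock) with the number of hatchlings ``R`` they produced
(the recruits).  Both must be strictly positive because every downstream fit
works on ``ln`` or ``sqrt`` transforms of the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "AnnualRecord",
    "AbundanceSeries",
    "ClimateIndexSeries",
    "read_abundance",
    "write_abundance",
    "read_climate_index",
    "write_climate_index",
]


class SchemaError(ValueError):
    """A delimited file does not expose the expected columns."""


class ValidationError(ValueError):
    """Series content violates a domain invariant (positivity, ordering...)."""


@dataclass(frozen=True)
class AnnualRecord:
    """One year of observations: nesting females and the hatchlings produced."""

    year: int
    nesters: float
    hatchlings: float


# Column aliases accepted when no explicit column map is supplied.
_DEFAULT_ALIASES: Mapping[str, tuple[str, ...]] = {
    "year": ("year",),
    "nesters": ("nesters", "S", "females"),
    "hatchlings": ("hatchlings", "R"),
}


def _check_years(years: np.ndarray, what: str) -> None:
    if years.size == 0:
        raise ValidationError(f"{what}: empty series")
    diffs = np.diff(years)
    if np.any(diffs == 0):
        dup = int(years[1:][diffs == 0][0])
        raise ValidationError(f"{what}: duplicate year {dup}")
    if np.any(diffs < 0):
        raise ValidationError(f"{what}: years must be strictly increasing")


class AbundanceSeries:
    """Ordered annual (year, S, R) observations with positivity enforced.

    Parameters
    ----------
    years, nesters, hatchlings
        Equal-length sequences; years strictly increasing integers, counts
        strictly positive.
    """

    def __init__(
        self,
        years: Sequence[int],
        nesters: Sequence[float],
        hatchlings: Sequence[float],
    ) -> None:
        years_arr = np.asarray(years, dtype=int)
        s = np.asarray(nesters, dtype=float)
        r = np.asarray(hatchlings, dtype=float)
        if not (years_arr.size == s.size == r.size):
            raise ValidationError("years, nesters and hatchlings differ in length")
        if years_arr.size < 2:
            raise ValidationError("abundance series needs at least 2 years")
        _check_years(years_arr, "abundance series")
        for name, col in (("S (nesters)", s), ("R (hatchlings)", r)):
            bad = ~np.isfinite(col) | (col <= 0)
            if np.any(bad):
                yr = int(years_arr[bad][0])
                raise ValidationError(
                    f"{name} must be strictly positive; offending year: {yr}"
                )
        self.years = years_arr
        self.S = s
        self.R = r

    def __len__(self) -> int:
        return self.years.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceSeries):
            return NotImplemented
        return (
            np.array_equal(self.years, other.years)
            and np.array_equal(self.S, other.S)
            and np.array_equal(self.R, other.R)
        )

    @property
    def records(self) -> list[AnnualRecord]:
        return [
            AnnualRecord(int(y), float(s), float(r))
            for y, s, r in zip(self.years, self.S, self.R)
        ]

    @property
    def is_consecutive(self) -> bool:
        return bool(np.all(np.diff(self.years) == 1))

    def require_consecutive(self) -> None:
        if not self.is_consecutive:
            gaps = self.years[:-1][np.diff(self.years) > 1]
            missing: list[int] = []
            for g in gaps:
                nxt = self.years[self.years > g].min()
                missing.extend(range(int(g) + 1, int(nxt)))
            raise ValidationError(f"abundance series has gaps; missing years: {missing}")

    def subset(self, years: Iterable[int]) -> "AbundanceSeries":
        mask = np.isin(self.years, np.asarray(list(years), dtype=int))
        return AbundanceSeries(self.years[mask], self.S[mask], self.R[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "nesters": self.S, "hatchlings": self.R})


class ClimateIndexSeries:
    """Annual values of a sea-surface-temperature anomaly index."""

    def __init__(self, years: Sequence[int], values: Sequence[float]) -> None:
        years_arr = np.asarray(years, dtype=int)
        vals = np.asarray(values, dtype=float)
        if years_arr.size != vals.size:
            raise ValidationError("years and values differ in length")
        _check_years(years_arr, "climate index")
        gaps = np.flatnonzero(np.diff(years_arr) > 1)
        if gaps.size:
            missing: list[int] = []
            for i in gaps:
                missing.extend(range(int(years_arr[i]) + 1, int(years_arr[i + 1])))
            raise ValidationError(f"climate index has gaps; missing years: {missing}")
        if not np.all(np.isfinite(vals)):
            yr = int(years_arr[~np.isfinite(vals)][0])
            raise ValidationError(f"climate index has non-finite value at year {yr}")
        self.years = years_arr
        self.values = vals

    def __len__(self) -> int:
        return self.years.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClimateIndexSeries):
            return NotImplemented
        return np.array_equal(self.years, other.years) and np.array_equal(
            self.values, other.values
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})


def _resolve_column(df: pd.DataFrame, logical: str, columns: Mapping[str, str] | None) -> str:
    if columns is not None:
        name = columns.get(logical, logical)
        if name not in df.columns:
            raise SchemaError(f"column {name!r} (for {logical!r}) not found in header")
        return name
    for alias in _DEFAULT_ALIASES[logical]:
        if alias in df.columns:
            return alias
    raise SchemaError(
        f"no column for {logical!r}; expected one of {_DEFAULT_ALIASES[logical]}"
    )


def read_abundance(path, columns: Mapping[str, str] | None = None) -> AbundanceSeries:
    """Read an annual (year, nesters, hatchlings) CSV.

    ``columns`` optionally maps the logical names ``year``/``nesters``/
    ``hatchlings`` to the file's header names; by default common aliases
    (``S``, ``R``, ``females``) are also accepted.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    ycol = _resolve_column(df, "year", columns)
    scol = _resolve_column(df, "nesters", columns)
    rcol = _resolve_column(df, "hatchlings", columns)
    return AbundanceSeries(
        df[ycol].to_numpy(), df[scol].to_numpy(), df[rcol].to_numpy()
    )


def write_abundance(series: AbundanceSeries, path) -> None:
    # %.17g keeps read->write->read the identity on float64 counts
    series.to_frame().to_csv(path, index=False, float_format="%.17g")


def _coerce_numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        # +2: header line plus 1-based indexing
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValidationError(f"{path}: unparseable value in column {col!r} at line {line}")
    if out.isna().any():
        line = int(np.flatnonzero(out.isna().to_numpy())[0]) + 2
        raise ValidationError(f"{path}: missing value in column {col!r} at line {line}")
    return out.to_numpy(dtype=float)


def read_climate_index(path) -> ClimateIndexSeries:
    """Read a climate-index CSV, annual (year,value) or monthly (year,month,value).

    Monthly input is reduced to annual arithmetic means; every year must have
    all 12 months.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "year" not in cols:
        raise SchemaError("climate index file needs a 'year' column")
    if "month" in cols:
        vcol = next((c for c in cols if c not in ("year", "month")), None)
        if vcol is None:
            raise SchemaError("monthly climate file needs a value column")
        years = _coerce_numeric(df, "year", path).astype(int)
        months = _coerce_numeric(df, "month", path).astype(int)
        values = _coerce_numeric(df, vcol, path)
        annual_years = []
        annual_vals = []
        for yr in np.unique(years):
            got = np.sort(months[years == yr])
            if not np.array_equal(got, np.arange(1, 13)):
                want = sorted(set(range(1, 13)) - set(got.tolist()))
                raise ValidationError(
                    f"{path}: year {int(yr)} is missing month(s) {want}"
                )
            annual_years.append(int(yr))
            annual_vals.append(float(values[years == yr].mean()))
        return ClimateIndexSeries(annual_years, annual_vals)
    vcol = next((c for c in cols if c != "year"), None)
    if vcol is None:
        raise SchemaError("annual climate file needs a value column")
    years = _coerce_numeric(df, "year", path).astype(int)
    values = _coerce_numeric(df, vcol, path)
    return ClimateIndexSeries(years, values)


def write_climate_index(series: ClimateIndexSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.17g")
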