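"""Daily mean-temperature forcing built from sparse maximum-temperature series.

Satellite land-surface products deliver a proxy for the daily *maximum*
temperature on an 8-day cadence.  The population model is forced by the daily
*mean* temperature, so preparation has three steps: (i) regress station mean
temperature on satellite maximum temperature where both exist,
``tmean = a * tmax + b``; (ii) interpolate the 8-day maxima linearly onto a
daily calendar grid; (iii) apply the regression to approximate daily means
everywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .thermal import CELSIUS_OFFSET

__all__ = [
    "TemperatureSeries",
    "TempRegression",
    "fit_mean_from_max",
    "interpolate_daily",
    "apply_regression",
]

#: Gaps longer than this (days) between valid 8-day observations trigger a
#: warning: linear interpolation across a season is unlikely to be faithful.
MAX_SILENT_GAP_DAYS = 32


@dataclass(frozen=True)
class TemperatureSeries:
    """A dated temperature series with an explicit unit tag.

    ``dates`` must be strictly increasing.  ``unit`` is ``"C"`` or ``"K"``.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    unit: str = "C"

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        if len(dates) != len(values):
            raise ValueError("dates and values must have equal length")
        if len(dates) > 1 and not dates.is_monotonic_increasing:
            raise ValueError("dates must be increasing")
        if len(dates) > 1 and dates.has_duplicates:
            raise ValueError("dates must be strictly increasing (duplicates found)")
        if self.unit not in ("C", "K"):
            raise ValueError(f"unit must be 'C' or 'K', got {self.unit!r}")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_daily(self) -> bool:
        if len(self.dates) < 2:
            return True
        return bool((np.diff(self.dates.asi8) == 86_400_000_000_000).all())

    def dropna(self) -> "TemperatureSeries":
        mask = np.isfinite(self.values)
        return replace(self, dates=self.dates[mask], values=self.values[mask])

    def to_kelvin(self) -> "TemperatureSeries":
        if self.unit == "K":
            return self
        return replace(self, values=self.values + CELSIUS_OFFSET, unit="K")

    def to_celsius(self) -> "TemperatureSeries":
        if self.unit == "C":
            return self
        return replace(self, values=self.values - CELSIUS_OFFSET, unit="C")

    def to_frame(self) -> pd.DataFrame:
        col = "temperature_C" if self.unit == "C" else "temperature_K"
        return pd.DataFrame({"date": self.dates, col: self.values})


@dataclass(frozen=True)
class TempRegression:
    """OLS link from maximum to mean temperature: ``tmean = slope*tmax + intercept``."""

    slope: float
    intercept: float
    r_squared: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("regression coefficients must be finite")


def fit_mean_from_max(tmax, tmean) -> TempRegression:
    """Ordinary least squares of mean temperature on maximum temperature.

    Both inputs are paired Celsius observations (station mean vs satellite
    maximum at the calibration site).  Requires at least three pairs and a
    non-constant predictor.
    """
    x = np.asarray(tmax, dtype=float)
    y = np.asarray(tmean, dtype=float)
    if x.shape != y.shape:
        raise ValueError("tmax and tmean must be paired (equal length)")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: maximum-temperature predictor is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    return TempRegression(slope=float(slope), intercept=float(intercept),
                          r_squared=float(model.rsquared))


def interpolate_daily(series: TemperatureSeries) -> TemperatureSeries:
    """Linearly interpolate a sparse series onto the daily calendar grid.

    Missing (NaN) values are dropped before interpolation; knot values are
    preserved exactly.  Already-daily series are returned unchanged.
    """
    clean = series.dropna()
    if len(clean) < 2:
        raise ValueError("cannot interpolate a series with fewer than 2 valid points")
    gaps = np.diff(clean.dates.asi8) / 86_400_000_000_000
    if np.any(gaps > MAX_SILENT_GAP_DAYS):
        warnings.warn(
            f"temperature series has a gap of {int(gaps.max())} days; linear "
            "interpolation over long gaps may distort the seasonal forcing",
            stacklevel=2,
        )
    if clean.is_daily:
        return clean
    daily_dates = pd.date_range(clean.dates[0], clean.dates[-1], freq="D")
    daily_values = np.interp(
        daily_dates.asi8.astype(float),
        clean.dates.asi8.astype(float),
        clean.values,
    )
    return TemperatureSeries(dates=daily_dates, values=daily_values, unit=clean.unit)


def apply_regression(series: TemperatureSeries, reg: TempRegression) -> TemperatureSeries:
    """Map a maximum-temperature series through ``tmean = a*tmax + b``.

    The regression is fitted on Celsius data, so the series must be in
    Celsius; the unit is preserved.
    """
    if series.unit != "C":
        raise ValueError("apply_regression expects a Celsius series; convert first")
    return replace(series, values=reg.slope * series.values + reg.intercept)
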