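"""Trend estimation, driver correlation, and SST gradient fields."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scene import Grid

METRES_PER_DEGREE = 111195.0  # length of one degree of latitude


@dataclass(frozen=True)
class TrendResult:
    """Slope, two-sided p-value and correlation diagnostics of an annual
    series (or of one series against another)."""

    slope: float
    intercept: float
    p_value: float
    r: float
    n: int


def _clean_pairs(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


def linear_trend(series, years=None) -> TrendResult:
    """Ordinary least-squares trend of an annual series vs year.

    The p-value is the two-sided t-test on the slope.  Requires at least
    three finite values.
    """
    series = np.asarray(series, dtype=float)
    if years is None:
        years = np.arange(series.size, dtype=float)
    x, y = _clean_pairs(years, series)
    if x.size < 3:
        raise ValueError("need at least 3 finite values for a trend")
    if np.allclose(y, y[0]):
        return TrendResult(0.0, float(y[0]), 1.0, 0.0, int(x.size))
    res = stats.linregress(x, y)
    return TrendResult(
        float(res.slope), float(res.intercept), float(res.pvalue),
        float(res.rvalue), int(x.size),
    )


def correlate(a, b) -> TrendResult:
    """Pearson correlation between two annual series (pairwise-complete),
    with the two-sided p-value; slope/intercept are those of b regressed on
    a."""
    x, y = _clean_pairs(a, b)
    if x.size < 3:
        raise ValueError("need at least 3 pairwise-complete values")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for a constant series")
    res = stats.linregress(x, y)
    return TrendResult(
        float(res.slope), float(res.intercept), float(res.pvalue),
        float(res.rvalue), int(x.size),
    )


def sst_gradient(sst: np.ndarray, grid: Grid) -> np.ndarray:
    """Magnitude of the horizontal SST gradient (degC per metre).

    Central differences in the interior, one-sided at the edges; metric
    distances from spherical geometry (one degree of latitude = 111195 m,
    one degree of longitude scaled by cos(latitude)).  Accepts a 2-D field
    or a stack with the last two axes (lat, lon).
    """
    sst = np.asarray(sst, dtype=float)
    if sst.shape[-2:] != grid.shape or min(grid.shape) < 3:
        raise ValueError("need a >= 3x3 raster matching the grid")
    lat_m = grid.lat * METRES_PER_DEGREE
    dTdy = np.gradient(sst, lat_m, axis=-2)
    dTdx_deg = np.gradient(sst, grid.lon, axis=-1)
    coslat = np.cos(np.deg2rad(grid.lat))
    shape = [1] * sst.ndim
    shape[-2] = grid.lat.size
    dTdx = dTdx_deg / (METRES_PER_DEGREE * coslat.reshape(shape))
    return np.sqrt(dTdx**2 + dTdy**2)


def day_of_year_365(date: _dt.date) -> int:
    """Day of year on a 365-day calendar; 29 February folds into day 59."""
    doy = date.timetuple().tm_yday
    if date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0):
        if doy == 60:  # 29 Feb
            return 59
        if doy > 60:
            return doy - 1
    return doy


def windowed_mean(
    dates: list[_dt.date], fields: np.ndarray, window: tuple[int, int]
) -> pd.Series:
    """Per-year mean of a daily field series over a day-of-year window.

    ``window = (start, end)`` in days 1-365; a wrapped window (start > end)
    selects days >= start or <= end.  The field mean is taken over finite
    values of all window days of the year; returns a Series indexed by year.
    """
    start, end = window
    fields = np.asarray(fields, dtype=float)
    if fields.shape[0] != len(dates):
        raise ValueError("dates and field stack lengths differ")
    doys = np.array([day_of_year_365(d) for d in dates])
    years = np.array([d.year for d in dates])
    if start <= end:
        in_window = (doys >= start) & (doys <= end)
    else:
        in_window = (doys >= start) | (doys <= end)
    out = {}
    for year in np.unique(years):
        sel = in_window & (years == year)
        if not sel.any():
            out[int(year)] = np.nan
            continue
        out[int(year)] = float(np.nanmean(fields[sel]))
    return pd.Series(out, name="windowed_mean")
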