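"""Threshold-based climate suitability scoring.

An epiphyte with no root contact with soil experiences the atmosphere
directly, so its physiological envelope can be written as four
thresholds on sub-daily weather: minimum temperature at least 5 degC,
maximum temperature at most 35 degC, relative humidity at least 50 %,
and no run of 15 or more consecutive rainless days. Each threshold is
evaluated per calendar day from four 6-hourly observations:

* temperature / humidity: a day is unsuitable when two *consecutive*
  observations fall strictly outside the limit (an observation exactly
  at the limit is optimal);
* rainless days: a day with all four precipitation observations at (or
  below a configurable trace of) zero is rainless; a day is unsuitable
  when it terminates a run of ``rainless_run_limit`` rainless days.

Percent time unsuitable for a month window is the share of unsuitable
days among all days of those calendar months across the requested
years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import MonthWindow

__all__ = [
    "VARIABLES",
    "PhysiologyThresholds",
    "SuitabilityResult",
    "saturation_vapour_pressure",
    "relative_humidity",
    "day_unsuitable_by_threshold",
    "rainless_day",
    "rainless_unsuitable_flags",
    "DailyFlags",
    "compute_daily_flags",
    "percent_time_unsuitable",
    "monthly_suitable_fraction",
]

#: The four physiological variables, in canonical order.
VARIABLES = ("min_temp", "max_temp", "rel_humidity", "rainless")

# Magnus-type constants of the saturation vapour pressure fit (hPa, degC).
_ES_A = 6.112
_ES_B = 17.502
_ES_C = 240.97


@dataclass(frozen=True)
class PhysiologyThresholds:
    """Optimal-range limits, inclusive on the optimal side.

    ``tmin_limit_c`` — minimum temperature optimal when >= limit (degC).
    ``tmax_limit_c`` — maximum temperature optimal when <= limit (degC).
    ``rh_limit`` — relative humidity optimal when >= limit (fraction).
    ``rainless_run_limit`` — unsuitable when a run of this many
    consecutive rainless days occurs (days).
    ``trace_mm`` — precipitation at or below this amount counts as zero
    (a 6-h observation, millimetres); exact zero by default, raise it
    for reanalysis products that drizzle.
    """

    tmin_limit_c: float = 5.0
    tmax_limit_c: float = 35.0
    rh_limit: float = 0.5
    rainless_run_limit: int = 15
    trace_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.tmin_limit_c >= self.tmax_limit_c:
            raise ValueError("tmin_limit_c must be below tmax_limit_c")
        if not 0.0 < self.rh_limit < 1.0:
            raise ValueError("rh_limit must be in (0, 1)")
        if self.rainless_run_limit < 1:
            raise ValueError("rainless_run_limit must be >= 1")
        if self.trace_mm < 0:
            raise ValueError("trace_mm must be non-negative")


@dataclass(frozen=True)
class SuitabilityResult:
    cell_id: int
    variable: str
    window: MonthWindow
    percent_unsuitable: float
    n_days: int


def saturation_vapour_pressure(temperature_c):
    """Saturation vapour pressure in hPa at a temperature in degC.

    Magnus-type fit ``6.112 * exp(17.502 T / (240.97 + T))``; strictly
    positive and strictly increasing on its domain ``T > -240.97``.
    """
    t = np.asarray(temperature_c, dtype=float)
    if np.any(t <= -_ES_C):
        raise ValueError(f"temperature at or below {-_ES_C} degC")
    out = _ES_A * np.exp(_ES_B * t / (_ES_C + t))
    return float(out) if np.isscalar(temperature_c) else out


def relative_humidity(dewpoint_c, temperature_c):
    """Relative humidity as es(dew point) / es(air temperature).

    Equals 1 when the dew point matches the air temperature and stays
    at or below 1 whenever the dew point does not exceed it.
    """
    return saturation_vapour_pressure(dewpoint_c) / saturation_vapour_pressure(
        temperature_c
    )


def _pairwise_outside(obs: np.ndarray, limit: float, side: str, axis: int = -1):
    if side == "below":
        outside = obs < limit
    elif side == "above":
        outside = obs > limit
    else:
        raise ValueError(f"side must be 'below' or 'above', got {side!r}")
    a = np.take(outside, range(0, outside.shape[axis] - 1), axis=axis)
    b = np.take(outside, range(1, outside.shape[axis]), axis=axis)
    return np.any(a & b, axis=axis)


def day_unsuitable_by_threshold(obs, limit: float, side: str) -> bool:
    """Flag one day from its four observations against one limit.

    True when some adjacent pair of observations is strictly outside
    the limit on the given side (``"below"`` or ``"above"``). A value
    exactly at the limit is inside the optimal range.
    """
    arr = np.asarray(obs, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"expected exactly 4 observations, got shape {arr.shape}")
    return bool(_pairwise_outside(arr, limit, side))


def rainless_day(precip, trace: float = 0.0) -> bool:
    """True when all four precipitation observations are at or below trace."""
    arr = np.asarray(precip, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"expected exactly 4 observations, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("negative precipitation")
    return bool(np.all(arr <= trace))


def rainless_unsuitable_flags(rainless: np.ndarray, run_limit: int) -> np.ndarray:
    """Per-day unsuitability from daily rainless flags.

    Day ``d`` is flagged when the ``run_limit`` days ending at ``d``
    are all rainless; the first ``run_limit - 1`` days can never be
    flagged. Works on a 1-D day series or on a (day, ...) stack.
    """
    if run_limit < 1:
        raise ValueError("run_limit must be >= 1")
    r = np.asarray(rainless, dtype=bool)
    counts = np.cumsum(r, axis=0, dtype=np.int64)
    out = np.zeros_like(r)
    if r.shape[0] >= run_limit:
        window_sum = counts[run_limit - 1 :].copy()
        window_sum[1:] -= counts[: r.shape[0] - run_limit]
        out[run_limit - 1 :] = window_sum == run_limit
    return out


@dataclass
class DailyFlags:
    """Daily unsuitability flags per variable on the full grid.

    ``flags[v]`` has shape (n_days, n_lat, n_lon); ``days`` is the
    per-day timestamp index. Computed once per series and reused for
    every window and candidate window.
    """

    days: pd.DatetimeIndex
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def months(self) -> np.ndarray:
        return self.days.month.to_numpy()

    @property
    def years(self) -> np.ndarray:
        return self.days.year.to_numpy()


def _obs_by_day(values: np.ndarray, n_days: int) -> np.ndarray:
    # (time, ...) -> (day, 4, ...)
    return values.reshape((n_days, 4) + values.shape[1:])


def compute_daily_flags(series, thresholds: PhysiologyThresholds) -> DailyFlags:
    """Daily unsuitability for all four variables over the whole grid.

    ``series`` is a :class:`~phenoclim.climate_io.ClimateSeries` (or any
    object with ``.time`` and degC/mm arrays ``mn2t``/``mx2t``/``t2m``/
    ``d2m``/``tp`` shaped (time, lat, lon) at four observations per day
    starting at 00 h).
    """
    time = pd.DatetimeIndex(series.time)
    if len(time) % 4 != 0 or time[0].hour != 0:
        raise ValueError("series must hold four observations per day from 00 h")
    n_days = len(time) // 4
    days = time[::4].normalize()

    mn = _obs_by_day(series.mn2t, n_days)
    mx = _obs_by_day(series.mx2t, n_days)
    t2m = _obs_by_day(series.t2m, n_days)
    d2m = _obs_by_day(series.d2m, n_days)
    tp = _obs_by_day(series.tp, n_days)
    if np.any(tp < 0):
        raise ValueError("negative precipitation in series")

    rh = relative_humidity(d2m, t2m)
    dry_days = np.all(tp <= thresholds.trace_mm, axis=1)

    flags = {
        "min_temp": _pairwise_outside(mn, thresholds.tmin_limit_c, "below", axis=1),
        "max_temp": _pairwise_outside(mx, thresholds.tmax_limit_c, "above", axis=1),
        "rel_humidity": _pairwise_outside(rh, thresholds.rh_limit, "below", axis=1),
        "rainless": rainless_unsuitable_flags(
            dry_days, thresholds.rainless_run_limit
        ),
    }
    return DailyFlags(days=days, flags=flags)


def _day_mask(daily: DailyFlags, window: MonthWindow, years) -> np.ndarray:
    in_window = np.isin(daily.months, window.months())
    if years is not None:
        year_set = np.asarray(sorted(set(int(y) for y in years)))
        present = np.unique(daily.years)
        if not np.any(np.isin(present, year_set)):
            raise ValueError("requested years do not intersect the series span")
        in_window &= np.isin(daily.years, year_set)
    return in_window


def percent_time_unsuitable(
    series,
    cell_id: int,
    variable: str,
    thresholds: PhysiologyThresholds,
    window: MonthWindow,
    years=None,
    daily: DailyFlags | None = None,
) -> SuitabilityResult:
    """Percent of days unsuitable for one variable over a month window.

    The window's calendar months are pooled across all requested years
    (cross-year windows such as Nov-Apr accumulate by month membership,
    ignoring the year boundary). Pass a precomputed ``daily`` flag set
    to avoid rescoring the series for each candidate window.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    if daily is None:
        daily = compute_daily_flags(series, thresholds)
    row, col = series.grid.row_col(cell_id)
    mask = _day_mask(daily, window, years)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no days fall inside the requested window and years")
    unsuitable = int(daily.flags[variable][mask, row, col].sum())
    return SuitabilityResult(
        cell_id=cell_id,
        variable=variable,
        window=window,
        percent_unsuitable=100.0 * unsuitable / n,
        n_days=n,
    )


def monthly_suitable_fraction(
    daily: DailyFlags, variable: str, years=None
) -> np.ndarray:
    """Fraction of suitable days per calendar month, shape (12, lat, lon).

    The month axis is calendar months 1..12 pooled across years; feeds
    the per-(cell, month) optimality share summary.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    flags = daily.flags[variable]
    months = daily.months
    sel = np.ones(len(months), dtype=bool)
    if years is not None:
        sel = np.isin(daily.years, np.asarray(sorted(set(int(y) for y in years))))
    out = np.full((12,) + flags.shape[1:], np.nan)
    for m in range(1, 13):
        mask = sel & (months == m)
        if mask.any():
            out[m - 1] = 1.0 - flags[mask].mean(axis=0)
    return out
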