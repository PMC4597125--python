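"""Threshold scoring: humidity formula, daily flags, percent-time oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoclim.suitability import (
    PhysiologyThresholds,
    compute_daily_flags,
    day_unsuitable_by_threshold,
    monthly_suitable_fraction,
    percent_time_unsuitable,
    rainless_day,
    rainless_unsuitable_flags,
    relative_humidity,
    saturation_vapour_pressure,
)
from phenoclim.windows import MonthWindow

from conftest import build_series


# --- independent loop-based oracle -----------------------------------------

def oracle_percent(series, cell_id, variable, thr, window, years):
    """Day-by-day pure-Python re-implementation of the scoring rules."""
    arrays = series.cell_arrays(cell_id)
    time = series.time
    n_days = len(time) // 4
    day_flags, day_month, day_year, rainless = [], [], [], []
    for d in range(n_days):
        sl = slice(4 * d, 4 * d + 4)
        ts = time[4 * d]
        day_month.append(ts.month)
        day_year.append(ts.year)
        if variable == "min_temp":
            obs, limit, side = arrays["mn2t"][sl], thr.tmin_limit_c, "below"
        elif variable == "max_temp":
            obs, limit, side = arrays["mx2t"][sl], thr.tmax_limit_c, "above"
        elif variable == "rel_humidity":
            obs = [
                (6.112 * math.exp(17.502 * td / (240.97 + td)))
                / (6.112 * math.exp(17.502 * ta / (240.97 + ta)))
                for td, ta in zip(arrays["d2m"][sl], arrays["t2m"][sl])
            ]
            limit, side = thr.rh_limit, "below"
        else:
            rainless.append(all(p <= thr.trace_mm for p in arrays["tp"][sl]))
            continue
        flag = False
        for i in range(3):
            a, b = obs[i], obs[i + 1]
            outside = (a < limit and b < limit) if side == "below" else (
                a > limit and b > limit
            )
            flag = flag or outside
        day_flags.append(flag)
    if variable == "rainless":
        L = thr.rainless_run_limit
        day_flags = [
            d >= L - 1 and all(rainless[d - L + 1 : d + 1])
            for d in range(n_days)
        ]
    months = set(window.months())
    sel = [
        i
        for i in range(n_days)
        if day_month[i] in months and (years is None or day_year[i] in years)
    ]
    return 100.0 * sum(day_flags[i] for i in sel) / len(sel)


# --- saturation vapour pressure and relative humidity -----------------------

class TestHumidityFormula:
    def test_zero_celsius_reference_value(self):
        assert saturation_vapour_pressure(0.0) == pytest.approx(6.112, abs=1e-12)

    def test_closed_form_at_20(self):
        expected = 6.112 * math.exp(17.502 * 20.0 / (240.97 + 20.0))
        assert saturation_vapour_pressure(20.0) == pytest.approx(expected, rel=1e-14)

    @given(st.floats(-60, 60), st.floats(0.01, 40))
    def test_strictly_increasing(self, t, dt):
        assert saturation_vapour_pressure(t) < saturation_vapour_pressure(t + dt)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            saturation_vapour_pressure(-240.97)

    def test_rh_identity_and_subsaturation(self):
        assert relative_humidity(15.0, 15.0) == pytest.approx(1.0)
        assert relative_humidity(5.0, 10.0) < 1.0
        expected = (
            saturation_vapour_pressure(10.0) / saturation_vapour_pressure(25.0)
        )
        assert relative_humidity(10.0, 25.0) == pytest.approx(expected, rel=1e-14)

    @given(st.floats(-30, 40), st.floats(0, 25))
    def test_rh_in_unit_interval_when_dew_below_air(self, ta, depression):
        rh = relative_humidity(ta - depression, ta)
        assert 0.0 < rh <= 1.0 + 1e-12


# --- per-day flagging rules --------------------------------------------------

class TestDayFlags:
    @pytest.mark.parametrize(
        "obs,limit,side,expected",
        [
            ([4, 4, 10, 10], 5, "below", True),  # adjacent pair below
            ([4, 10, 4, 10], 5, "below", False),  # alternating, no pair
            ([5, 5, 5, 5], 5, "below", False),  # at-limit is optimal
            ([10, 10, 36, 36], 35, "above", True),
            ([36, 35, 36, 35], 35, "above", False),
            ([10, 4, 4, 10], 5, "below", True),  # middle pair
        ],
    )
    def test_two_consecutive_rule(self, obs, limit, side, expected):
        assert day_unsuitable_by_threshold(obs, limit, side) is expected

    def test_wrong_observation_count(self):
        with pytest.raises(ValueError):
            day_unsuitable_by_threshold([1, 2, 3], 5, "below")

    @pytest.mark.parametrize(
        "precip,trace,expected",
        [
            ([0, 0, 0, 0], 0.0, True),
            ([0, 0, 0.2, 0], 0.0, False),
            ([0.05, 0, 0, 0], 0.1, True),  # trace rule
        ],
    )
    def test_rainless_day(self, precip, trace, expected):
        assert rainless_day(precip, trace) is expected

    def test_negative_precipitation_rejected(self):
        with pytest.raises(ValueError):
            rainless_day([0, -0.1, 0, 0])


class TestRainlessRuns:
    def test_fourteen_dry_then_rain_never_flags(self):
        flags = rainless_unsuitable_flags(
            np.array([True] * 14 + [False]), run_limit=15
        )
        assert not flags.any()

    def test_exactly_fifteen_flags_last_day(self):
        flags = rainless_unsuitable_flags(np.array([True] * 15), run_limit=15)
        assert flags.tolist() == [False] * 14 + [True]

    def test_twenty_dry_days_flag_six(self):
        flags = rainless_unsuitable_flags(np.array([True] * 20), run_limit=15)
        assert int(flags.sum()) == 6
        assert flags[14:].all() and not flags[:14].any()

    @given(st.lists(st.booleans(), min_size=1, max_size=60), st.integers(1, 20))
    @settings(max_examples=100, deadline=None)
    def test_matches_window_enumeration(self, dry, limit):
        """Each day's flag equals the brute-force scan of trailing windows."""
        flags = rainless_unsuitable_flags(np.array(dry), run_limit=limit)
        for d in range(len(dry)):
            expected = d >= limit - 1 and all(dry[d - limit + 1 : d + 1])
            assert bool(flags[d]) == expected


# --- percent time unsuitable -------------------------------------------------

class TestPercentTimeUnsuitable:
    def test_constant_suitable_climate_scores_zero(self, grid1):
        series = build_series(grid1, "2001-01-01", 60)
        thr = PhysiologyThresholds()
        for variable in ("min_temp", "max_temp", "rel_humidity", "rainless"):
            res = percent_time_unsuitable(
                series, 0, variable, thr, MonthWindow(1, 2)
            )
            assert res.percent_unsuitable == 0.0

    def test_frozen_climate_scores_hundred_for_min_temp(self, grid1):
        series = build_series(grid1, "2001-01-01", 31, mn2t=0.0)
        res = percent_time_unsuitable(
            series, 0, "min_temp", PhysiologyThresholds(), MonthWindow(1, 1)
        )
        assert res.percent_unsuitable == 100.0

    def test_half_cold_january_scores_fifty(self, grid1):
        """Alternate days with two consecutive sub-5 observations -> 50 %."""
        mn = np.full(31 * 4, 10.0)
        for d in range(0, 31, 2):  # 16 of 31 days cold
            mn[4 * d : 4 * d + 2] = 0.0
        series = build_series(grid1, "2001-01-01", 31, mn2t=mn)
        res = percent_time_unsuitable(
            series, 0, "min_temp", PhysiologyThresholds(), MonthWindow(1, 1)
        )
        assert res.percent_unsuitable == pytest.approx(100.0 * 16 / 31)
        # and the independent oracle agrees exactly
        assert res.percent_unsuitable == oracle_percent(
            series, 0, "min_temp", PhysiologyThresholds(), MonthWindow(1, 1), None
        )

    def test_empty_window_years_rejected(self, grid1):
        series = build_series(grid1, "2001-01-01", 40)
        with pytest.raises(ValueError):
            percent_time_unsuitable(
                series, 0, "min_temp", PhysiologyThresholds(),
                MonthWindow(1, 1), years=[1999],
            )

    def test_random_series_match_loop_oracle(self, grid1):
        """Vectorized scoring equals the loop oracle on 50 random series."""
        rng = np.random.default_rng(123)
        thr = PhysiologyThresholds(trace_mm=0.05)
        for trial in range(50):
            n_days = int(rng.integers(20, 101))
            n_t = 4 * n_days
            series = build_series(
                grid1,
                "2001-01-01",
                n_days,
                mn2t=rng.uniform(-5, 15, n_t),
                mx2t=rng.uniform(25, 45, n_t),
                t2m=rng.uniform(10, 30, n_t),
                d2m=rng.uniform(-5, 25, n_t),
                tp=np.where(rng.random(n_t) < 0.5, 0.0, rng.exponential(2, n_t)),
            )
            window = MonthWindow(1, int(rng.integers(1, 4)))  # Jan always present
            daily = compute_daily_flags(series, thr)
            for variable in ("min_temp", "max_temp", "rel_humidity", "rainless"):
                got = percent_time_unsuitable(
                    series, 0, variable, thr, window, daily=daily
                ).percent_unsuitable
                want = oracle_percent(series, 0, variable, thr, window, None)
                assert got == pytest.approx(want, abs=1e-9), (trial, variable)

    def test_raising_tmin_limit_is_monotone(self, grid1):
        rng = np.random.default_rng(5)
        series = build_series(
            grid1, "2001-01-01", 90, mn2t=rng.uniform(-5, 15, 360)
        )
        pcts = [
            percent_time_unsuitable(
                series, 0, "min_temp",
                PhysiologyThresholds(tmin_limit_c=lim), MonthWindow(1, 3),
            ).percent_unsuitable
            for lim in (0.0, 5.0, 10.0, 14.0)
        ]
        assert pcts == sorted(pcts)

    def test_longer_rainless_limit_never_flags_more(self, grid1):
        rng = np.random.default_rng(6)
        tp = np.where(rng.random(360) < 0.7, 0.0, 1.0)
        series = build_series(grid1, "2001-01-01", 90, tp=tp)
        pcts = [
            percent_time_unsuitable(
                series, 0, "rainless",
                PhysiologyThresholds(rainless_run_limit=lim), MonthWindow(1, 3),
            ).percent_unsuitable
            for lim in (2, 5, 10, 15)
        ]
        assert pcts == sorted(pcts, reverse=True)

    def test_window_day_count_is_calendar_exact(self, grid1):
        """Feb days across 2003-2005 include the 2004 leap day."""
        series = build_series(grid1, "2003-01-01", 365 + 366 + 365)
        res = percent_time_unsuitable(
            series, 0, "min_temp", PhysiologyThresholds(), MonthWindow(2, 1)
        )
        assert res.n_days == 28 + 29 + 28

    def test_cross_year_window_pools_by_month(self, grid1):
        series = build_series(grid1, "2001-01-01", 365)
        res = percent_time_unsuitable(
            series, 0, "min_temp", PhysiologyThresholds(), MonthWindow(11, 4)
        )
        assert res.n_days == 30 + 31 + 31 + 28  # Nov, Dec, Jan, Feb of 2001

    def test_monthly_suitable_fraction(self, grid1):
        mn = np.full(4 * 59, 10.0)
        mn[: 4 * 31] = 0.0  # all of January cold, February fine
        series = build_series(grid1, "2001-01-01", 59, mn2t=mn)
        daily = compute_daily_flags(series, PhysiologyThresholds())
        frac = monthly_suitable_fraction(daily, "min_temp")
        assert frac[0, 0, 0] == 0.0
        assert frac[1, 0, 0] == 1.0
        assert np.isnan(frac[5, 0, 0])  # June absent from the series
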