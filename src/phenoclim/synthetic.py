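"""Synthetic ERA-like climate and herbarium-style specimen tables.

The generator stands in for two data sources that cannot ship with the
package: a 6-hourly reanalysis archive and a digitized herbarium
occurrence table. It plants a known flowering season per coarse grid
cell (the ground truth) so that every downstream stage — window
construction, suitability scoring, ranking, distance mapping — can be
tested for parameter recovery.

Climate model, per 1.5 deg cell and independent across cells:

* temperature = sinusoidal annual cycle + sinusoidal diurnal cycle
  (minimum at 00 h, maximum at 12 h) + AR(1) noise shared by the three
  temperature variables; ``mn2t <= t2m <= mx2t`` is enforced by
  clamping after noise;
* dew point = mean temperature minus a non-negative seasonal
  depression, so relative humidity never exceeds 1;
* precipitation = per-day Bernoulli wet-day draw with a monthly
  probability, wet-day amounts exponential, the whole amount landing
  on one random 6-h observation.

The calendar is the real Gregorian calendar with leap days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate_io import ClimateSeries
from .grid import GridSpec
from .windows import MonthWindow

__all__ = [
    "SeasonalCycle",
    "ClimateGenParams",
    "CellTruth",
    "FloweringTruth",
    "generate_climate",
    "generate_specimens",
    "params_for_truth",
    "write_truth_json",
    "read_truth_json",
    "write_specimen_csv",
]


@dataclass(frozen=True)
class SeasonalCycle:
    """A sinusoidal annual cycle peaking at ``phase_month``.

    ``phase_month`` may be a scalar or an (n_lat, n_lon) array to vary
    the peak per cell (used to plant per-cell seasons).
    """

    mean: float
    amplitude: float = 0.0
    phase_month: float | np.ndarray = 7.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def evaluate(self, year_fraction: np.ndarray) -> np.ndarray:
        """Value at fractional positions within the year (0..1)."""
        peak = (np.asarray(self.phase_month, dtype=float) - 0.5) / 12.0
        frac = np.asarray(year_fraction)[(...,) + (None,) * np.ndim(peak)]
        return self.mean + self.amplitude * np.cos(2 * np.pi * (frac - peak))


@dataclass(frozen=True)
class ClimateGenParams:
    """Parameters of the synthetic climate generator.

    Defaults sketch a humid subtropical cell (US Gulf-coast flavour):
    mild winters that still dip below the 5 degC minimum-temperature
    limit, summers short of the 35 degC maximum, moist air year round
    and frequent rain. ``wet_day_prob`` is one Bernoulli probability
    per calendar month.
    """

    tmean: SeasonalCycle = field(
        default_factory=lambda: SeasonalCycle(mean=20.0, amplitude=8.0)
    )
    tmin: SeasonalCycle = field(
        default_factory=lambda: SeasonalCycle(mean=14.0, amplitude=9.0)
    )
    tmax: SeasonalCycle = field(
        default_factory=lambda: SeasonalCycle(mean=26.0, amplitude=8.0)
    )
    diurnal_amplitude: float = 3.0
    ar1_coef: float = 0.7
    ar1_sd: float = 1.5
    dew_depression: SeasonalCycle = field(
        default_factory=lambda: SeasonalCycle(mean=3.0, amplitude=1.5, phase_month=1.0)
    )
    wet_day_prob: tuple[float, ...] = (0.35,) * 12
    wet_day_scale_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diurnal_amplitude < 0:
            raise ValueError("diurnal_amplitude must be non-negative")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.ar1_sd < 0:
            raise ValueError("ar1_sd must be non-negative")
        if len(self.wet_day_prob) != 12 or any(
            not 0.0 <= p <= 1.0 for p in self.wet_day_prob
        ):
            raise ValueError("wet_day_prob needs 12 probabilities in [0, 1]")
        if self.wet_day_scale_mm <= 0:
            raise ValueError("wet_day_scale_mm must be positive")


def _year_fraction(time: pd.DatetimeIndex) -> np.ndarray:
    days_in_year = np.where(time.is_leap_year, 366.0, 365.0)
    return (time.dayofyear.to_numpy() - 1 + time.hour.to_numpy() / 24.0) / days_in_year


def _ar1(rng: np.random.Generator, n_t: int, shape: tuple, coef: float, sd: float):
    if sd == 0.0:
        return np.zeros((n_t,) + shape)
    innov = rng.standard_normal((n_t,) + shape) * sd
    out = np.empty_like(innov)
    out[0] = innov[0] / np.sqrt(max(1.0 - coef**2, 1e-12))
    for t in range(1, n_t):
        out[t] = coef * out[t - 1] + innov[t]
    return out


def generate_climate(
    grid: GridSpec, start_year: int, n_years: int, params: ClimateGenParams
) -> ClimateSeries:
    """Simulate a 6-hourly series over whole calendar years.

    Four observations per day (00/06/12/18 h) on the real Gregorian
    calendar. The same seed and parameters give bit-identical output.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    time = pd.date_range(
        start=f"{start_year}-01-01",
        end=f"{start_year + n_years - 1}-12-31 18:00",
        freq="6h",
    )
    n_t = len(time)
    shape = (grid.n_lat, grid.n_lon)
    frac = _year_fraction(time)
    diurnal = -params.diurnal_amplitude * np.cos(
        2 * np.pi * time.hour.to_numpy() / 24.0
    )
    diurnal = diurnal[(...,) + (None,) * 2]

    rng = np.random.default_rng(params.seed)
    noise = _ar1(rng, n_t, shape, params.ar1_coef, params.ar1_sd)

    def seasonal(cycle: SeasonalCycle) -> np.ndarray:
        vals = cycle.evaluate(frac)
        if vals.ndim == 1:  # scalar phase: broadcast over the grid
            vals = vals[:, None, None]
        return np.broadcast_to(vals, (n_t,) + shape)

    t2m = seasonal(params.tmean) + diurnal + noise
    mn2t = np.minimum(seasonal(params.tmin) + diurnal + noise, t2m)
    mx2t = np.maximum(seasonal(params.tmax) + diurnal + noise, t2m)
    d2m = t2m - np.maximum(seasonal(params.dew_depression), 0.0)

    # precipitation: one Bernoulli wet-day draw per day per cell
    n_days = n_t // 4
    month_per_day = time[::4].month.to_numpy()
    wet_p = np.asarray(params.wet_day_prob)[month_per_day - 1]
    wet = rng.random((n_days,) + shape) < wet_p[:, None, None]
    amounts = rng.exponential(params.wet_day_scale_mm, (n_days,) + shape) * wet
    slot = rng.integers(0, 4, (n_days,) + shape)
    tp = np.zeros((n_days, 4) + shape)
    np.put_along_axis(tp, slot[:, None], amounts[:, None], axis=1)
    tp = tp.reshape((n_t,) + shape)

    return ClimateSeries(
        grid=grid, time=time, mn2t=mn2t, mx2t=mx2t, t2m=t2m, d2m=d2m, tp=tp
    )


@dataclass(frozen=True)
class CellTruth:
    """Planted flowering season and sampling regime for one 3 deg cell."""

    window: MonthWindow
    intensity: float = 4.5  # expected specimen records in the cell
    concentration: float = 0.9  # probability a record's month is in-window
    imprecision: float = 0.5  # fraction of records with month-only dates

    def __post_init__(self) -> None:
        for name in ("intensity",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("concentration", "imprecision"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class FloweringTruth:
    """Ground truth keyed by 3 deg cell id."""

    cells: dict[int, CellTruth]

    @classmethod
    def uniform(
        cls,
        grid3: GridSpec,
        seed: int,
        length: int = 3,
        intensity: float = 4.5,
        concentration: float = 0.9,
        imprecision: float = 0.5,
    ) -> "FloweringTruth":
        """Random start month per cell, shared window length and regime."""
        rng = np.random.default_rng(seed)
        cells = {
            cid: CellTruth(
                window=MonthWindow(int(rng.integers(1, 13)), length),
                intensity=intensity,
                concentration=concentration,
                imprecision=imprecision,
            )
            for cid in range(grid3.n_cells)
        }
        return cls(cells=cells)


def params_for_truth(
    grid: GridSpec,
    truth: FloweringTruth,
    base: ClimateGenParams | None = None,
) -> ClimateGenParams:
    """Align the minimum-temperature peak with each planted window.

    Returns parameters whose seasonal cycles peak, cell by cell on the
    1.5 deg grid, at the centre month of the parent 3 deg cell's true
    window, so the planted season is the warmest of the year there.
    """
    from dataclasses import replace

    from .grid import parent_3deg

    base = base or ClimateGenParams()
    phase = np.empty((grid.n_lat, grid.n_lon))
    for cid in range(grid.n_cells):
        row, col = grid.row_col(cid)
        tw = truth.cells[parent_3deg(cid, grid)].window
        centre = tw.start_month - 1 + (tw.length - 1) / 2.0
        phase[row, col] = centre % 12 + 1
    return replace(
        base,
        tmean=replace(base.tmean, phase_month=phase),
        tmin=replace(base.tmin, phase_month=phase),
        tmax=replace(base.tmax, phase_month=phase),
    )


def generate_specimens(
    truth: FloweringTruth, grid: GridSpec, start_year: int, n_years: int, seed: int
) -> pd.DataFrame:
    """Draw a specimen occurrence table from the planted truth.

    One Poisson(intensity) count per 3 deg cell; each record gets a
    uniform location inside the cell, a uniform year, a month drawn
    in-window with probability ``concentration`` (uniform within /
    outside the window), a day that is blank with probability
    ``imprecision``, and a flowering or fruiting phenophase.
    """
    if grid.n_cells == 0:
        raise ValueError("empty grid")
    grid3 = grid.coarsen(3.0)
    rng = np.random.default_rng(seed)
    rows = []
    for cid in sorted(truth.cells):
        cell = truth.cells[cid]
        n = int(rng.poisson(cell.intensity))
        if n == 0:
            continue
        lon0, lon1, lat0, lat1 = grid3.cell_bounds(cid)
        in_months = list(cell.window.months())
        out_months = [m for m in range(1, 13) if m not in in_months]
        for _ in range(n):
            lon = float(rng.uniform(lon0, lon1))
            lat = float(rng.uniform(lat0, lat1))
            year = int(rng.integers(start_year, start_year + n_years))
            if not out_months or rng.random() < cell.concentration:
                month = int(rng.choice(in_months))
            else:
                month = int(rng.choice(out_months))
            if rng.random() < cell.imprecision:
                day = None
            else:
                day = int(rng.integers(1, 29))
            phase = "flowering" if rng.random() < 0.7 else "fruiting"
            rows.append((lon, lat, year, month, day, phase))
    df = pd.DataFrame(
        rows,
        columns=["longitude_dd", "latitude_dd", "year", "month", "day", "phenophase"],
    )
    df.insert(0, "record_id", [f"SYN{index:05d}" for index in range(len(df))])
    return df


def write_specimen_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_truth_json(truth: FloweringTruth, path) -> None:
    payload = {
        str(cid): {
            "start_month": cell.window.start_month,
            "length": cell.window.length,
            "intensity": cell.intensity,
            "concentration": cell.concentration,
            "imprecision": cell.imprecision,
        }
        for cid, cell in sorted(truth.cells.items())
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth_json(path) -> FloweringTruth:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    cells = {
        int(cid): CellTruth(
            window=MonthWindow(entry["start_month"], entry["length"]),
            intensity=entry["intensity"],
            concentration=entry["concentration"],
            imprecision=entry["imprecision"],
        )
        for cid, entry in payload.items()
    }
    return FloweringTruth(cells=cells)
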