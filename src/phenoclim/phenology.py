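"""Flowering windows from specimen occurrence records.

Herbarium records give sparse month-resolution evidence of when a
population flowers or fruits. Records are pooled on a 3 deg grid (the
climate stays at 1.5 deg), the flowering period per cell is the
shortest cyclic arc of consecutive months covering every observed
month (temporal gaps filled under a unimodality assumption), and the
average flowering month is a specimen-count-weighted circular mean.

Flowering and fruiting records are pooled by default; pass a
phenophase filter to restrict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, assign_cell
from .windows import MonthWindow

__all__ = [
    "FloweringProfile",
    "read_specimen_csv",
    "fill_unimodal",
    "weighted_mean_month",
    "build_profiles",
    "profiles_to_frame",
]

log = logging.getLogger(__name__)

# Darwin-Core-style header aliases accepted on read.
_COLUMN_ALIASES = {
    "decimallongitude": "longitude_dd",
    "decimallatitude": "latitude_dd",
    "reproductivecondition": "phenophase",
}


@dataclass(frozen=True)
class FloweringProfile:
    """Flowering window of one 3 deg cell.

    ``mean_month`` is real-valued on (0, 12] (circular by default) and
    ``None`` when the circular mean is undefined (perfectly antipodal
    month counts).
    """

    cell3_id: int
    month_counts: tuple[int, ...]  # specimens per calendar month, Jan..Dec
    window: MonthWindow
    mean_month: float | None
    n_specimens: int


def read_specimen_csv(path) -> pd.DataFrame:
    """Read a specimen table, normalizing Darwin-Core header aliases.

    ``eventDate`` (ISO year-month or year-month-day) is split into
    year/month/day when explicit columns are absent. Records without a
    month are dropped with a warning; day-of-month is carried but never
    used (the analysis is month-resolution).
    """
    df = pd.read_csv(path)
    df = df.rename(
        columns={c: _COLUMN_ALIASES.get(c.lower(), c) for c in df.columns}
    )
    if "month" not in df.columns and "eventDate" in df.columns:
        dates = pd.to_datetime(df["eventDate"], errors="coerce")
        df["year"] = dates.dt.year
        df["month"] = dates.dt.month
        df["day"] = dates.dt.day
    required = {"longitude_dd", "latitude_dd", "month"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimen table lacks columns: {sorted(missing)}")
    n_before = len(df)
    df = df[df["month"].notna()].copy()
    if len(df) < n_before:
        log.warning("dropped %d records without a month", n_before - len(df))
    df["month"] = df["month"].astype(int)
    if not df["month"].between(1, 12).all():
        raise ValueError("month values outside 1..12")
    return df.reset_index(drop=True)


def fill_unimodal(month_counts) -> MonthWindow:
    """Shortest cyclic arc of consecutive months covering all records.

    Gaps inside the arc are filled (a Mar + May cell gets Mar-May);
    when two arcs tie in length the one starting at the earlier
    calendar month wins. A single observed month gives a length-1
    window.
    """
    counts = np.asarray(month_counts)
    if counts.shape != (12,):
        raise ValueError("month_counts must have 12 entries (Jan..Dec)")
    present = np.flatnonzero(counts > 0) + 1
    if present.size == 0:
        raise ValueError("no months with specimens")
    best: MonthWindow | None = None
    for start in present:
        length = int(max((m - start) % 12 for m in present)) + 1
        cand = MonthWindow(int(start), length)
        if (
            best is None
            or cand.length < best.length
            or (cand.length == best.length and cand.start_month < best.start_month)
        ):
            best = cand
    return best


def weighted_mean_month(month_counts, mode: str = "circular") -> float | None:
    """Specimen-count-weighted average flowering month on (0, 12].

    ``circular`` (default) maps month m to the angle 2*pi*(m - 0.5)/12,
    averages the unit vectors with the counts as weights, and maps the
    resultant angle back, so windows wrapping the year boundary average
    correctly (Dec + Feb -> January, not July). Returns ``None`` when
    the resultant vector vanishes (antipodal counts). ``arithmetic``
    is the plain weighted mean of month numbers.
    """
    counts = np.asarray(month_counts, dtype=float)
    if counts.shape != (12,):
        raise ValueError("month_counts must have 12 entries (Jan..Dec)")
    if counts.sum() <= 0:
        raise ValueError("no months with specimens")
    months = np.arange(1, 13)
    if mode == "arithmetic":
        return float((months * counts).sum() / counts.sum())
    if mode != "circular":
        raise ValueError(f"unknown mean-month mode {mode!r}")
    theta = 2 * np.pi * (months - 0.5) / 12.0
    x = (counts * np.cos(theta)).sum()
    y = (counts * np.sin(theta)).sum()
    if np.hypot(x, y) < 1e-9 * counts.sum():
        return None
    mean = (np.arctan2(y, x) / (2 * np.pi) * 12.0 + 0.5) % 12.0
    return 12.0 if mean == 0.0 else float(mean)


def build_profiles(
    specimens: pd.DataFrame,
    grid: GridSpec,
    phenophase: str | None = None,
    mean_month_mode: str = "circular",
) -> dict[int, FloweringProfile]:
    """Aggregate records into per-3 deg-cell flowering profiles.

    Every record lands in exactly one 3 deg cell; the per-cell window
    comes from :func:`fill_unimodal` and the mean month from
    :func:`weighted_mean_month`. ``phenophase`` restricts to
    ``"flowering"`` or ``"fruiting"`` records (pooled when ``None``).
    """
    df = specimens
    if phenophase is not None:
        df = df[df["phenophase"] == phenophase]
    grid3 = grid.coarsen(3.0)
    cell_ids = np.array(
        [
            assign_cell(lon, lat, grid3)
            for lon, lat in zip(df["longitude_dd"], df["latitude_dd"])
        ],
        dtype=int,
    )
    profiles: dict[int, FloweringProfile] = {}
    for cid in sorted(set(cell_ids.tolist())):
        months = df["month"].to_numpy()[cell_ids == cid]
        counts = np.bincount(months, minlength=13)[1:13]
        profiles[cid] = FloweringProfile(
            cell3_id=cid,
            month_counts=tuple(int(c) for c in counts),
            window=fill_unimodal(counts),
            mean_month=weighted_mean_month(counts, mode=mean_month_mode),
            n_specimens=int(counts.sum()),
        )
    return profiles


def profiles_to_frame(profiles: dict[int, FloweringProfile]) -> pd.DataFrame:
    """Flatten profiles to a table with the per-month count matrix."""
    rows = []
    for cid, p in sorted(profiles.items()):
        rows.append(
            {
                "cell3_id": cid,
                "window_start": p.window.start_month,
                "window_length": p.window.length,
                "mean_month": p.mean_month,
                "n_specimens": p.n_specimens,
                **{f"m{m:02d}": p.month_counts[m - 1] for m in range(1, 13)},
            }
        )
    return pd.DataFrame(rows)
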