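"""Gridded 6-hourly climate series and their NetCDF dialect.

On disk the series uses the ERA-Interim surface-variable names and
units: ``mn2t``, ``mx2t``, ``t2m``, ``d2m`` in kelvin and ``tp`` in
metres accumulated per 6 h step, on dimensions (time, lat, lon) with
time in hours since an epoch and a ``standard`` calendar. In memory
temperatures are degC and precipitation is millimetres per 6 h — the
units the physiological thresholds are stated in.

Files are NETCDF3_CLASSIC written through xarray's scipy backend;
the dialect round-trips through any CF-aware reader.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec

__all__ = ["ClimateSeries", "write_netcdf", "read_netcdf"]

KELVIN_OFFSET = 273.15
TEMP_VARS = ("mn2t", "mx2t", "t2m", "d2m")
_SIX_HOURS = pd.Timedelta(hours=6)


@dataclass
class ClimateSeries:
    """6-hourly climate fields on a regular lat/lon grid.

    Arrays are shaped (time, lat, lon) with latitude rows north to
    south, matching :class:`~phenoclim.grid.GridSpec` cell indexing.
    Temperatures are degC, ``tp`` is mm per 6 h.
    """

    grid: GridSpec
    time: pd.DatetimeIndex
    mn2t: np.ndarray
    mx2t: np.ndarray
    t2m: np.ndarray
    d2m: np.ndarray
    tp: np.ndarray

    def __post_init__(self) -> None:
        self.time = pd.DatetimeIndex(self.time)
        if len(self.time) < 2:
            raise ValueError("series needs at least two time steps")
        steps = np.diff(self.time.to_numpy())
        if not np.all(steps == np.timedelta64(6, "h")):
            raise ValueError("time axis must increase in constant 6 h steps")
        shape = (len(self.time), self.grid.n_lat, self.grid.n_lon)
        for name in (*TEMP_VARS, "tp"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )

    @property
    def years(self) -> range:
        return range(int(self.time[0].year), int(self.time[-1].year) + 1)

    def cell_arrays(self, cell_id: int) -> dict[str, np.ndarray]:
        """Per-variable 1-D time series of one cell."""
        row, col = self.grid.row_col(cell_id)
        return {
            name: getattr(self, name)[:, row, col]
            for name in (*TEMP_VARS, "tp")
        }


def _grid_from_coords(lat: np.ndarray, lon: np.ndarray) -> GridSpec:
    """Recover the GridSpec from cell-center coordinates."""
    if len(lon) > 1:
        cell = float(abs(lon[1] - lon[0]))
    elif len(lat) > 1:
        cell = float(abs(lat[1] - lat[0]))
    else:
        raise ValueError("cannot infer cell size from a single-cell grid")
    half = cell / 2
    return GridSpec(
        lon_min=float(lon.min() - half),
        lon_max=float(lon.max() + half),
        lat_min=float(lat.min() - half),
        lat_max=float(lat.max() + half),
        cell_size=cell,
    )


def write_netcdf(series: ClimateSeries, path) -> None:
    """Write a series in the ERA-style kelvin/metre NetCDF dialect."""
    ds = xr.Dataset(
        {
            **{
                name: (
                    ("time", "lat", "lon"),
                    getattr(series, name) + KELVIN_OFFSET,
                    {"units": "K"},
                )
                for name in TEMP_VARS
            },
            "tp": (("time", "lat", "lon"), series.tp / 1000.0, {"units": "m"}),
        },
        coords={
            "time": ("time", series.time),
            "lat": ("lat", series.grid.lat_centers(), {"units": "degrees_north"}),
            "lon": ("lon", series.grid.lon_centers(), {"units": "degrees_east"}),
        },
        attrs={"Conventions": "CF-1.6"},
    )
    ds["mn2t"].attrs["long_name"] = "Minimum temperature at 2 metres"
    ds["mx2t"].attrs["long_name"] = "Maximum temperature at 2 metres"
    ds["t2m"].attrs["long_name"] = "2 metre temperature"
    ds["d2m"].attrs["long_name"] = "2 metre dewpoint temperature"
    ds["tp"].attrs["long_name"] = "Total precipitation per 6 h"
    encoding = {
        "time": {
            "units": "hours since 1900-01-01 00:00:00",
            "calendar": "standard",
            "dtype": "float64",
        }
    }
    ds.to_netcdf(path, engine="scipy", encoding=encoding)


def read_netcdf(path) -> ClimateSeries:
    """Read the dialect back, converting kelvin to degC and metres to mm.

    Latitude rows are reordered north to south when the file stores
    them ascending. Missing variables or a broken 6 h cadence raise.
    """
    with xr.open_dataset(path, engine="scipy", decode_times=True) as ds:
        ds.load()
    missing = [v for v in (*TEMP_VARS, "tp") if v not in ds]
    if missing:
        raise ValueError(f"climate file lacks variables: {missing}")
    if float(ds.lat[0]) < float(ds.lat[-1]):
        ds = ds.isel(lat=slice(None, None, -1))
    lat = ds.lat.to_numpy()
    lon = ds.lon.to_numpy()
    grid = _grid_from_coords(lat, lon)
    time = pd.DatetimeIndex(ds.time.to_numpy())
    fields = {
        name: ds[name].to_numpy().astype(float) - KELVIN_OFFSET
        for name in TEMP_VARS
    }
    fields["tp"] = ds["tp"].to_numpy().astype(float) * 1000.0
    return ClimateSeries(grid=grid, time=time, **fields)
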