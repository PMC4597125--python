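"""Shared fixtures: tiny grids and hand-built climate series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from phenoclim.climate_io import ClimateSeries
from phenoclim.grid import GridSpec


@pytest.fixture
def grid1() -> GridSpec:
    """Single 3-degree block of four 1.5-degree cells."""
    return GridSpec(-90.0, -87.0, 30.0, 33.0, 1.5)


@pytest.fixture
def grid_4x4() -> GridSpec:
    """A 6 x 6 degree extent: 4 x 4 climate cells, 2 x 2 phenology cells."""
    return GridSpec(-90.0, -84.0, 30.0, 36.0, 1.5)


def build_series(
    grid: GridSpec,
    start: str,
    n_days: int,
    mn2t=10.0,
    mx2t=20.0,
    t2m=15.0,
    d2m=12.0,
    tp=1.0,
) -> ClimateSeries:
    """Climate series from per-observation values.

    Each field may be a scalar (constant everywhere) or an array of
    length ``4 * n_days`` broadcast over all cells.
    """
    n_t = 4 * n_days
    time = pd.date_range(start=start, periods=n_t, freq="6h")
    shape = (n_t, grid.n_lat, grid.n_lon)

    def expand(v):
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            return np.full(shape, float(arr))
        assert arr.shape == (n_t,)
        return np.broadcast_to(arr[:, None, None], shape).copy()

    return ClimateSeries(
        grid=grid,
        time=time,
        mn2t=expand(mn2t),
        mx2t=expand(mx2t),
        t2m=expand(t2m),
        d2m=expand(d2m),
        tp=expand(tp),
    )


@pytest.fixture
def build_series_fn():
    return build_series
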