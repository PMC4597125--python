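"""Regular lat/lon grids for climate cells and coarser phenology cells.

Cells live on a regular lattice anchored at the southwest corner of the
extent (``lon_min``, ``lat_min``) but are *indexed* row-major from the
northwest corner, matching the row order of the gridded climate fields.
Cell membership uses the half-open convention ``[edge, edge + cell_size)``
on both axes; points exactly on the east/north boundary of the extent are
clamped into the last cell so the extent is fully covered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["GridSpec", "assign_cell", "parent_3deg"]


@dataclass(frozen=True)
class GridSpec:
    """A regular latitude/longitude lattice.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max
        Extent edges in decimal degrees. Each span must be a positive
        integer multiple of ``cell_size``.
    cell_size
        Cell edge length in degrees (1.5 for the climate grid, 3.0 for
        the phenology grid).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float = 1.5

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        for span, name in (
            (self.lon_max - self.lon_min, "longitude"),
            (self.lat_max - self.lat_min, "latitude"),
        ):
            n = span / self.cell_size
            if span <= 0 or abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"{name} span {span} is not a positive multiple of "
                    f"cell_size {self.cell_size}"
                )

    @property
    def n_lon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.cell_size)

    @property
    def n_lat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.cell_size)

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, west to east."""
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (row order)."""
        return self.lat_max - (np.arange(self.n_lat) + 0.5) * self.cell_size

    def cell_id(self, row: int, col: int) -> int:
        """Row-major id; row 0 is the northernmost band."""
        if not (0 <= row < self.n_lat and 0 <= col < self.n_lon):
            raise ValueError(f"cell ({row}, {col}) outside grid")
        return row * self.n_lon + col

    def row_col(self, cell_id: int) -> tuple[int, int]:
        if not 0 <= cell_id < self.n_cells:
            raise ValueError(f"cell id {cell_id} outside grid")
        return divmod(cell_id, self.n_lon)

    def cell_center(self, cell_id: int) -> tuple[float, float]:
        """(lon, lat) center of a cell."""
        row, col = self.row_col(cell_id)
        return (float(self.lon_centers()[col]), float(self.lat_centers()[row]))

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of one cell."""
        lon_c, lat_c = self.cell_center(cell_id)
        h = self.cell_size / 2
        return (lon_c - h, lon_c + h, lat_c - h, lat_c + h)

    def coarsen(self, cell_size: float) -> "GridSpec":
        """Same extent at a coarser resolution (e.g. 1.5 deg -> 3 deg)."""
        return replace(self, cell_size=cell_size)


def assign_cell(lon: float, lat: float, grid: GridSpec) -> int:
    """Map a point to its cell id under the half-open edge convention.

    Points exactly on the extent's east or north boundary are clamped
    into the last cell; points outside the extent raise ``ValueError``.
    """
    if not (grid.lon_min <= lon <= grid.lon_max):
        raise ValueError(f"longitude {lon} outside extent")
    if not (grid.lat_min <= lat <= grid.lat_max):
        raise ValueError(f"latitude {lat} outside extent")
    col = min(int((lon - grid.lon_min) / grid.cell_size), grid.n_lon - 1)
    # rows count from the north; the half-open rule applies from the south
    from_south = min(int((lat - grid.lat_min) / grid.cell_size), grid.n_lat - 1)
    row = grid.n_lat - 1 - from_south
    return grid.cell_id(row, col)


def parent_3deg(cell_id: int, grid: GridSpec) -> int:
    """Id of the 3 deg cell containing a 1.5 deg cell.

    Both grids share the extent, so each 3 deg cell aggregates exactly a
    2x2 block of 1.5 deg cells. Requires the extent to be a multiple of
    3 deg and ``grid.cell_size == 1.5``.
    """
    if abs(grid.cell_size - 1.5) > 1e-9:
        raise ValueError("parent_3deg expects a 1.5 degree grid")
    coarse = grid.coarsen(3.0)  # validates that extents are multiples of 3
    row, col = grid.row_col(cell_id)
    return coarse.cell_id(row // 2, col // 2)
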