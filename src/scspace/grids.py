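"""Regular lat/lon grids and latitude-dependent cell areas.

Every raster in a run lives on one :class:`GridSpec`: a regular WGS84
lat/lon grid, cell-center registered, row 0 = northernmost row, longitudes
in [-180, 180). Cell areas come from the spherical-cap formula, so zonal
sums and per-100-km2 densities are area-true without a projection step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0
TROPIC_LAT = 23.5


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic grid (cell-center registration, north-up).

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape; row 0 is the northernmost row.
    lat_min, lat_max : float
        Outer latitude bounds of the grid (cell edges), degrees.
    lon_min, lon_max : float
        Outer longitude bounds (cell edges), degrees in [-180, 180].
    """

    n_rows: int
    n_cols: int
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not (self.lat_max > self.lat_min):
            raise ValueError("lat_max must exceed lat_min")
        if not (self.lon_max > self.lon_min):
            raise ValueError("lon_max must exceed lon_min")
        if self.lat_min < -90 or self.lat_max > 90:
            raise ValueError("latitudes must lie in [-90, 90]")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_rows

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_cols

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, row 0 first (north to south)."""
        edges = np.linspace(self.lat_max, self.lat_min, self.n_rows + 1)
        return (edges[:-1] + edges[1:]) / 2.0

    @property
    def lon_centers(self) -> np.ndarray:
        edges = np.linspace(self.lon_min, self.lon_max, self.n_cols + 1)
        return (edges[:-1] + edges[1:]) / 2.0

    @property
    def lat_edges(self) -> np.ndarray:
        """Latitude cell edges from north to south, length n_rows + 1."""
        return np.linspace(self.lat_max, self.lat_min, self.n_rows + 1)

    def lat_field(self) -> np.ndarray:
        """(n_rows, n_cols) array of cell-center latitudes."""
        return np.broadcast_to(
            self.lat_centers[:, None], self.shape
        ).copy()


def cell_areas(spec: GridSpec) -> np.ndarray:
    """Per-cell area in km2 via the spherical-cap formula.

    area = R^2 * dlon_rad * (sin(lat_top) - sin(lat_bottom)), constant
    along a row and decreasing toward the poles. Summed over a full-globe
    grid this reproduces 4*pi*R^2 to machine precision.
    """
    edges = np.deg2rad(spec.lat_edges)
    band = np.sin(edges[:-1]) - np.sin(edges[1:])  # north edge minus south edge
    row_area = EARTH_RADIUS_KM**2 * np.deg2rad(spec.dlon) * band
    return np.broadcast_to(row_area[:, None], spec.shape).copy()


def tropics_mask(spec: GridSpec, limit: float = TROPIC_LAT) -> np.ndarray:
    """Boolean mask of cells whose center latitude satisfies |lat| <= limit."""
    return np.abs(spec.lat_field()) <= limit
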