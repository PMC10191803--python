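"""Planar grid geometry shared by covariate layers and prediction surfaces.

All coordinates are planar kilometres; there is no geodesy. A grid is a
regular lattice of square cells; layer arrays are indexed ``[row, col]``
with row 0 at the southern (low-y) edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import box


@dataclass(frozen=True)
class GridGeometry:
    """Origin-anchored regular grid of square cells.

    Parameters
    ----------
    x0, y0 : float
        Coordinates of the lower-left corner (km).
    resolution : float
        Cell edge length (km).
    nx, ny : int
        Number of columns and rows.
    """

    x0: float
    y0: float
    resolution: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("grid resolution must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.resolution,
            self.y0 + self.ny * self.resolution,
        )

    @property
    def diameter(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return float(np.hypot(xmax - xmin, ymax - ymin))

    def polygon(self):
        """Domain rectangle as a shapely polygon."""
        return box(*self.extent)

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-centre coordinates, row-major."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.resolution
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.resolution
        xg, yg = np.meshgrid(xs, ys)
        return np.column_stack([xg.ravel(), yg.ravel()])

    def cell_index(self, points: np.ndarray) -> np.ndarray:
        """Row-major flat cell index of each (x, y) point; clipped to edges."""
        pts = np.asarray(points, dtype=float)
        col = np.clip(
            np.floor((pts[:, 0] - self.x0) / self.resolution).astype(int), 0, self.nx - 1
        )
        row = np.clip(
            np.floor((pts[:, 1] - self.y0) / self.resolution).astype(int), 0, self.ny - 1
        )
        return row * self.nx + col

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        return (
            (pts[:, 0] >= xmin)
            & (pts[:, 0] <= xmax)
            & (pts[:, 1] >= ymin)
            & (pts[:, 1] <= ymax)
        )

    def coarsen_to(self, resolution: float) -> "GridGeometry":
        """A new grid over the same extent at a different resolution."""
        xmin, ymin, xmax, ymax = self.extent
        nx = max(1, int(round((xmax - xmin) / resolution)))
        ny = max(1, int(round((ymax - ymin) / resolution)))
        return GridGeometry(xmin, ymin, resolution, nx, ny)
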