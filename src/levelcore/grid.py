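"""Raster grid geometry.

Convention: origin at the lower-left corner; row 0 is the southernmost row;
cell (i, j) has center (x0 + (j + 0.5) * cell, y0 + (i + 0.5) * cell).
Points map to cells by floor((x - x0) / cell); points on the exact right or
top edge belong to the last cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    x0: float
    y0: float
    cellsize: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cellsize <= 0 or self.nrows < 1 or self.ncols < 1:
            raise GridError("invalid grid dimensions")

    @property
    def xmax(self) -> float:
        return self.x0 + self.ncols * self.cellsize

    @property
    def ymax(self) -> float:
        return self.y0 + self.nrows * self.cellsize

    @property
    def cell_area(self) -> float:
        return self.cellsize ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.nrows) + 0.5) * self.cellsize

    def point_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices for points; exact right/top edges clamp inward."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        inside = ((x >= self.x0) & (x <= self.xmax)
                  & (y >= self.y0) & (y <= self.ymax))
        if not np.all(inside):
            raise GridError("point outside grid extent")
        col = np.minimum(np.floor((x - self.x0) / self.cellsize).astype(int),
                         self.ncols - 1)
        row = np.minimum(np.floor((y - self.y0) / self.cellsize).astype(int),
                         self.nrows - 1)
        return row, col

    def covers(self, points: np.ndarray, margin: float = 0.0) -> bool:
        """True if every point lies at least ``margin`` inside the extent."""
        pts = np.asarray(points, float)
        return bool(np.all((pts[:, 0] >= self.x0 + margin)
                           & (pts[:, 0] <= self.xmax - margin)
                           & (pts[:, 1] >= self.y0 + margin)
                           & (pts[:, 1] <= self.ymax - margin)))

    @classmethod
    def from_points(cls, points: np.ndarray, cellsize: float,
                    margin: float) -> "GridSpec":
        """Smallest grid covering the points with the requested margin."""
        pts = np.asarray(points, float)
        x0 = float(pts[:, 0].min() - margin)
        y0 = float(pts[:, 1].min() - margin)
        ncols = int(np.ceil((pts[:, 0].max() + margin - x0) / cellsize)) or 1
        nrows = int(np.ceil((pts[:, 1].max() + margin - y0) / cellsize)) or 1
        return cls(x0=x0, y0=y0, cellsize=cellsize, nrows=nrows, ncols=ncols)
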