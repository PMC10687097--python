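"""Planar raster grid geometry shared by every layer in a landscape.

All rasters in one analysis live on a single grid: ``n_rows x n_cols`` square
cells of ``cell_size`` km, anchored at ``(origin_x, origin_y)`` (the outer
corner of the top-left cell, row index increasing southwards). Pixel *centers*
carry the coordinates used for distances and point-in-pixel lookups, matching
the 1 km-grid semantics of the census-downscaling workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel stored in float rasters where no value is defined.
NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a raster grid with square cells.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; both at least 1.
    cell_size
        Cell edge length in km (grid cells are square).
    origin_x, origin_y
        Planar coordinates (km) of the top-left corner of pixel (0, 0).
    nodata
        Sentinel value written to float rasters outside the valid area.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area(self) -> float:
        """Area of one cell in km^2."""
        return self.cell_size ** 2

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all pixel centers, each of ``shape``."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def point_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map planar coordinates to (row, col) indices of the containing pixel."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def rowcol_to_point(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Planar coordinates of pixel centers for (row, col) indices."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def contains(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size": self.cell_size,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "nodata": self.nodata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            cell_size=float(d["cell_size"]),
            origin_x=float(d["origin_x"]),
            origin_y=float(d["origin_y"]),
            nodata=float(d.get("nodata", NODATA)),
        )


def check_same_geometry(a: GridGeometry, b: GridGeometry) -> None:
    """Raise ``ValueError`` unless the two grids are identical."""
    if a != b:
        raise ValueError(f"raster geometries differ: {a} vs {b}")


def valid_mask(raster: np.ndarray, nodata: float = NODATA) -> np.ndarray:
    """Boolean mask of pixels carrying data (finite and not the sentinel)."""
    arr = np.asarray(raster, dtype=float)
    return np.isfinite(arr) & (arr != nodata)
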