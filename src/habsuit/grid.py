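"""Lightweight georeferenced grid container.

All spatial layers in this package live on axis-aligned square-cell grids in
a projected CRS with meter units. Row 0 is the northernmost row; column 0 is
the westernmost column. Nodata is carried as NaN in memory and materialised
as a sentinel only on disk (ESRI ASCII grid, a plain-text raster format that
GDAL, QGIS and R's terra all read).

Geographic (degree) coordinates are deliberately unsupported: distance math
throughout the package assumes meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridRaster", "read_ascii_grid"]


@dataclass
class GridRaster:
    """A single-band raster on a square-cell grid.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values, float; NaN marks nodata. Row 0 is the top (north).
    x_min, y_min : float
        Coordinates of the lower-left corner of the grid, in meters.
    cell_size : float
        Cell edge length in meters (> 0).
    """

    values: np.ndarray
    x_min: float
    y_min: float
    cell_size: float
    name: str = field(default="layer")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.x_min + self.ncols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.nrows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max)."""
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row, descending) centers."""
        xs = self.x_min + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y_max - (np.arange(self.nrows) + 0.5) * self.cell_size
        return xs, ys

    def index_of(self, x, y):
        """Row/column of the cell containing each point.

        Points on a cell boundary belong to the cell to the east/south
        (half-open cells), except on the grid's outer east/north edge where
        the boundary point is assigned to the last cell.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.cell_size).astype(int)
        row = np.floor((self.y_max - y) / self.cell_size).astype(int)
        col = np.where((x == self.x_max), self.ncols - 1, col)
        row = np.where((y == self.y_min), self.nrows - 1, row)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x <= self.x_max)
            & (y >= self.y_min) & (y <= self.y_max)
        )

    def value_at(self, x, y) -> np.ndarray:
        """Nearest-cell (containing-cell) lookup; NaN outside the extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        row, col = self.index_of(np.clip(x, self.x_min, self.x_max),
                                 np.clip(y, self.y_min, self.y_max))
        out = self.values[row, col]
        return np.where(inside, out, np.nan)

    # -- construction helpers ---------------------------------------------
    def like(self, values: np.ndarray, name: str | None = None) -> "GridRaster":
        """New raster sharing this grid's georeferencing."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch with template grid")
        return GridRaster(values, self.x_min, self.y_min, self.cell_size,
                          name or self.name)

    def aligned_with(self, other: "GridRaster", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x_min - other.x_min) <= tol
            and abs(self.y_min - other.y_min) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    # -- I/O ----------------------------------------------------------------
    def write_ascii_grid(self, path, nodata: float = -9999.0) -> None:
        vals = np.where(np.isnan(self.values), nodata, self.values)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x_min!r}\n"
            f"yllcorner {self.y_min!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path, name: str = "layer") -> GridRaster:
    """Read an ESRI ASCII grid written by :meth:`GridRaster.write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return GridRaster(values, header["xllcorner"], header["yllcorner"],
                      header["cellsize"], name)
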