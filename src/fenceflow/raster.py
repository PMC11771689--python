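"""Gridded raster container and plain-text (ESRI ASCII grid) I/O.

A :class:`Raster` is the common currency between pipeline stages: habitat
suitability, movement resistance, and cumulative current are all single-band
grids on one shared projected frame. Row 0 is the northernmost row; ``origin``
is the (x, y) of the upper-left corner of the upper-left cell; all coordinates
are projected meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass
class Raster:
    """Single-band georeferenced grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, float. Cells equal to ``nodata`` (or NaN) are invalid.
    cell_size : float
        Cell edge length in meters; must be positive.
    origin : tuple of float
        (x, y) of the upper-left corner of the grid.
    nodata : float
        Sentinel marking invalid cells.
    meta : dict
        Free-form provenance metadata carried through operations.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = NODATA_DEFAULT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        ox, oy = self.origin
        return (ox, oy - self.nrows * self.cell_size, ox + self.ncols * self.cell_size, oy)

    def valid_mask(self) -> np.ndarray:
        v = self.values
        return np.isfinite(v) & (v != self.nodata)

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        ox, oy = self.origin
        x = ox + (np.asarray(col) + 0.5) * self.cell_size
        y = oy - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (xx, yy) of all cell-center coordinates."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.cell_center(rows, cols)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (may be out of range)."""
        ox, oy = self.origin
        col = np.floor((np.asarray(x, dtype=float) - ox) / self.cell_size).astype(int)
        row = np.floor((oy - np.asarray(y, dtype=float)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell value at each point; NaN outside the grid or on nodata."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full(x.shape, np.nan)
        inside = self.contains(x, y)
        row, col = self.index_of(x[inside], y[inside])
        row = np.clip(row, 0, self.nrows - 1)
        col = np.clip(col, 0, self.ncols - 1)
        vals = self.values[row, col]
        vals = np.where((vals == self.nodata) | ~np.isfinite(vals), np.nan, vals)
        out[inside] = vals
        return out

    def with_values(self, values: np.ndarray, **meta) -> "Raster":
        """New raster on the same grid with different values."""
        r = replace(self, values=np.asarray(values, dtype=float))
        r.meta = {**self.meta, **meta}
        return r

    def copy(self) -> "Raster":
        return replace(self, values=self.values.copy(), meta=dict(self.meta))


def grids_match(a: Raster, b: Raster, tol: float = 1e-9) -> bool:
    return (
        a.shape == b.shape
        and math.isclose(a.cell_size, b.cell_size, rel_tol=0, abs_tol=tol)
        and math.isclose(a.origin[0], b.origin[0], rel_tol=0, abs_tol=tol)
        and math.isclose(a.origin[1], b.origin[1], rel_tol=0, abs_tol=tol)
    )


def require_same_grid(a: Raster, b: Raster, names: tuple[str, str] = ("a", "b")) -> None:
    if not grids_match(a, b):
        raise ValueError(
            f"grid mismatch between '{names[0]}' {a.shape}@{a.cell_size} m origin {a.origin} "
            f"and '{names[1]}' {b.shape}@{b.cell_size} m origin {b.origin}"
        )


# -- plain-text raster I/O (ESRI ASCII grid) --------------------------------

def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write as ESRI ASCII grid (.asc), a plain-text interchange raster format."""
    path = Path(path)
    vals = np.where(np.isfinite(raster.values), raster.values, raster.nodata)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.origin[0]!r}\n"
        f"yllcorner {raster.origin[1] - raster.nrows * raster.cell_size!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    return path


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    values = values.reshape(nrows, ncols)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    values = np.where(values == nodata, np.nan, values)
    return Raster(values=values, cell_size=cell, origin=origin, nodata=nodata)
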