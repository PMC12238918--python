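"""Minimal planar raster container with ESRI ASCII grid I/O.

Coordinates are planar meters.  The grid origin (``x_origin``, ``y_origin``)
is the lower-left corner of the lower-left cell; row 0 is the southernmost
row and y increases with row index.  Cell centers sit at
``origin + (index + 0.5) * cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridRaster", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class GridRaster:
    """Rectangular georeferenced grid of cell values.

    Parameters
    ----------
    values
        2-D array, shape ``(nrows, ncols)``; row 0 is the southernmost row.
    x_origin, y_origin
        Lower-left corner of the grid in meters.
    cell_size
        Cell edge length in meters, > 0.
    nodata
        Sentinel for missing cells; must not collide with valid data.
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("GridRaster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def same_geometry(self, other: "GridRaster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin + (row + 0.5) * self.cell_size
        return x, y

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Cell index containing a point; raises if outside the grid."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((y - self.y_origin) / self.cell_size))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside grid")
        return row, col

    def like(self, values: np.ndarray, nodata: float | None = None) -> "GridRaster":
        """New raster sharing this grid's geometry."""
        return GridRaster(
            values=values,
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
            nodata=self.nodata if nodata is None else nodata,
        )

    def copy(self) -> "GridRaster":
        return self.like(self.values.copy())


def write_ascii_grid(raster: GridRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc).

    The format stores rows north-to-south, so the value block is our array
    flipped vertically.
    """
    path = Path(path)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.x_origin:.6f}\n"
        f"yllcorner {raster.y_origin:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata:.6f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values[::-1], fmt="%.8g")


def read_ascii_grid(path: str | Path) -> GridRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any
    conforming .asc file)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        values = np.loadtxt(fh, ndmin=2)
    nrows = int(header.get("nrows", values.shape[0]))
    ncols = int(header.get("ncols", values.shape[1]))
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: value block shape {values.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    return GridRaster(
        values=values[::-1].copy(),
        x_origin=header.get("xllcorner", 0.0),
        y_origin=header.get("yllcorner", 0.0),
        cell_size=header.get("cellsize", 1.0),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True
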