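"""Regular-grid containers and plain-text raster I/O.

Grids are plain 2-D numpy arrays tied to a :class:`GridSpec` describing a
north-up regular raster (origin at the upper-left corner, row 0 at the top).
Rasters are persisted as ESRI ASCII grids (``.asc``) so every artifact stays
text-only and readable without GIS dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from rwlr.errors import InterfaceError

__all__ = ["GridSpec", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up regular raster.

    ``origin_x``/``origin_y`` locate the *upper-left corner* of the grid;
    ``dx``/``dy`` are positive cell sizes; cell centres sit half a cell in.
    """

    nrows: int
    ncols: int
    dx: float = 1.0
    dy: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs: str = "local"

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) centre coordinates, each shaped (nrows, ncols)."""
        xs = self.origin_x + (np.arange(self.ncols) + 0.5) * self.dx
        ys = self.origin_y - (np.arange(self.nrows) + 0.5) * self.dy
        return np.meshgrid(xs, ys)

    def check_compatible(self, other: "GridSpec") -> None:
        if self.crs != other.crs:
            raise InterfaceError(f"CRS mismatch: {self.crs!r} vs {other.crs!r}")


def write_ascii_grid(path: str | Path, data: np.ndarray, grid: GridSpec,
                     nodata: float = -9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid (text raster)."""
    data = np.asarray(data, dtype=float)
    if data.shape != grid.shape:
        raise InterfaceError(f"data shape {data.shape} != grid shape {grid.shape}")
    out = np.where(np.isfinite(data), data, nodata)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin_x}\n"
        f"yllcorner {grid.origin_y - grid.nrows * grid.dy}\n"
        f"cellsize {grid.dx}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    cell = header["cellsize"]
    grid = GridSpec(
        nrows=nrows, ncols=ncols, dx=cell, dy=cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * cell,
    )
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return data, grid
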