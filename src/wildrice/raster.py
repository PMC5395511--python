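"""Single-band georeferenced grids and plain-text (ESRI ASCII) raster I/O.

Coordinates are WGS84 decimal degrees; the raster origin is the top-left
corner and cell values are referenced to cell centers. Nodata cells are
held as NaN in memory and materialised as the ``nodata_value`` token on
write.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class RasterGrid:
    """A single-band raster on a regular lon/lat grid.

    Parameters
    ----------
    values
        2-D array, row 0 at the top (northernmost). Nodata is NaN.
    xll, yll
        Lower-left *corner* of the grid, decimal degrees.
    cellsize
        Cell edge length in decimal degrees (square cells).
    nodata_value
        Sentinel written to disk for NaN cells.
    name
        Band name (e.g. the environmental variable it carries).
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata_value: float = -9999.0
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    # -- geometry -----------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer cell edges."""
        return (
            self.xll,
            self.xll + self.ncols * self.cellsize,
            self.yll,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude arrays of cell centers, shape (nrows, ncols)."""
        lon = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yll) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent")
        return row, col

    def sample(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Values at point locations (cell lookup, no interpolation)."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.full(lon.shape, np.nan)
        for i, (x, y) in enumerate(zip(lon, lat)):
            try:
                r, c = self.cell_index(x, y)
            except ValueError:
                continue
            out[i] = self.values[r, c]
        return out

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        """Copy of this grid carrying new values on the same georeference."""
        return replace(
            self, values=np.asarray(values, dtype=float),
            name=self.name if name is None else name,
        )

    def mask_like(self, other: "RasterGrid") -> "RasterGrid":
        """Propagate ``other``'s nodata cells into this grid."""
        vals = self.values.copy()
        vals[np.isnan(other.values)] = np.nan
        return self.with_values(vals)


def require_aligned(*grids: RasterGrid) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if not ref.aligned_with(g):
            raise ValueError("raster grids are not aligned (shape/origin/cellsize differ)")


# -- ESRI ASCII grid I/O ---------------------------------------------

def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    vals = np.where(np.isnan(grid.values), grid.nodata_value, grid.values)
    buf = io.StringIO()
    buf.write(f"ncols {grid.ncols}\n")
    buf.write(f"nrows {grid.nrows}\n")
    buf.write(f"xllcorner {grid.xll!r}\n")
    buf.write(f"yllcorner {grid.yll!r}\n")
    buf.write(f"cellsize {grid.cellsize!r}\n")
    buf.write(f"NODATA_value {grid.nodata_value!r}\n")
    np.savetxt(buf, vals, fmt="%.10g")
    Path(path).write_text(buf.getvalue())


def read_ascii_grid(path: str | Path, name: str = "") -> RasterGrid:
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    }:
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    vals = np.loadtxt(io.StringIO("\n".join(lines[i:])))
    vals = vals.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    return RasterGrid(
        values=vals,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata_value=nodata,
        name=name or Path(path).stem,
    )
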