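"""Planar raster grids with ESRI ASCII grid I/O.

Grids are stored north-up: row 0 is the northernmost row, and the cell
(r, c) center sits at ``(x_origin + (c + 0.5) * cell_size,
y_origin - (r + 0.5) * cell_size)`` where ``(x_origin, y_origin)`` is the
north-west corner of the grid. The on-disk format is the standard ESRI
ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value header
followed by the value matrix, north row first).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

_DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band georeferenced grid on a planar coordinate system."""

    values: np.ndarray
    x_origin: float = 0.0  # west edge
    y_origin: float = 0.0  # north edge
    cell_size: float = 30.0
    nodata: float = _DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid edge."""
        return (
            self.x_origin,
            self.y_origin - self.n_rows * self.cell_size,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin,
        )

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin - (row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (x, y) of all cell centers, shape (n_rows, n_cols)."""
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_center(rows, cols)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Cell indices containing planar points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def aligned_with(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
        )

    def like(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """A new grid sharing this grid's georeferencing."""
        return RasterGrid(
            values=np.asarray(values),
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
            nodata=self.nodata if nodata is None else nodata,
        )

    def mask_valid(self) -> np.ndarray:
        vals = self.values
        valid = np.isfinite(vals)
        if self.nodata is not None:
            valid &= vals != self.nodata
        return valid


def require_aligned(*grids: RasterGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.aligned_with(g):
            raise ValueError(
                "rasters are not aligned: "
                f"{first.shape}@{first.cell_size}m vs {g.shape}@{g.cell_size}m"
            )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc). NaN/inf become the nodata marker."""
    vals = np.array(grid.values, dtype=float)
    vals[~np.isfinite(vals)] = grid.nodata
    yll = grid.y_origin - grid.n_rows * grid.cell_size
    buf = io.StringIO()
    buf.write(f"ncols {grid.n_cols}\n")
    buf.write(f"nrows {grid.n_rows}\n")
    buf.write(f"xllcorner {grid.x_origin:.6f}\n")
    buf.write(f"yllcorner {yll:.6f}\n")
    buf.write(f"cellsize {grid.cell_size:.6f}\n")
    buf.write(f"NODATA_value {grid.nodata:g}\n")
    np.savetxt(buf, vals, fmt="%.8g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid. Nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner",
            "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII grid header missing '{key}': {path}")
    vals = np.loadtxt(io.StringIO("".join(lines[n_header:])), ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (nrows, ncols):
        raise ValueError(
            f"grid body shape {vals.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    vals[vals == nodata] = np.nan
    cell = header["cellsize"]
    return RasterGrid(
        values=vals,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=nodata,
    )
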