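"""Regular analysis grid and single-band raster container.

All spatial computation runs on one planar, axis-aligned grid of square
cells (default 100 m).  Coordinates are metres in an arbitrary projected
frame; row 0 is the southernmost row (origin at the lower-left corner).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class PointOutsideGridError(ValueError):
    """A queried point falls outside the grid extent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid.

    Parameters
    ----------
    origin:
        (x, y) of the lower-left corner of the lower-left cell, metres.
    n_rows, n_cols:
        Grid shape; row index increases northwards.
    cell_size:
        Cell edge length in metres (default 100).
    """

    origin: tuple[float, float]
    n_rows: int
    n_cols: int
    cell_size: float = 100.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return (x0, y0, x0 + self.width, y0 + self.height)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys) arrays of shape (n_rows, n_cols) of cell centers."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def point_to_cell(
        self, x: np.ndarray, y: np.ndarray, ids=None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) with the nearest-cell floor rule.

        Raises :class:`PointOutsideGridError` (naming the offending point)
        for coordinates outside the grid extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y - y0) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            i = int(np.argmax(bad))
            label = ids[i] if ids is not None else f"index {i}"
            raise PointOutsideGridError(
                f"point {label} at ({x.flat[i]:.1f}, {y.flat[i]:.1f}) "
                f"is outside the grid extent {self.bounds}"
            )
        return row, col

    def translate(self, dx: float, dy: float) -> "GridSpec":
        x0, y0 = self.origin
        return GridSpec((x0 + dx, y0 + dy), self.n_rows, self.n_cols, self.cell_size)


@dataclass
class Raster:
    """A single-band raster on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def sample(self, x, y, ids=None) -> np.ndarray:
        row, col = self.grid.point_to_cell(x, y, ids=ids)
        return self.values[row, col]

    def write_geotiff(self, path) -> None:
        write_geotiff(path, self)


def write_geotiff(path, raster: Raster) -> None:
    """Write a minimally georeferenced single-band float32 GeoTIFF.

    Embeds ModelPixelScale and ModelTiepoint tags; the CRS is left
    unspecified (planar metres).  Rows are flipped so that the file is
    north-up as GIS viewers expect.
    """
    import tifffile

    g = raster.grid
    x0, y0 = g.origin
    top = y0 + g.height
    data = np.flipud(np.asarray(raster.values, dtype=np.float32))
    extratags = [
        (33550, "d", 3, (g.cell_size, g.cell_size, 0.0)),  # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, x0, top, 0.0)),  # ModelTiepoint
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_geotiff(path, name: str = "") -> Raster:
    """Read a raster written by :func:`write_geotiff`."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        scale = page.tags[33550].value
        tiepoint = page.tags[33922].value
    cell = float(scale[0])
    n_rows, n_cols = data.shape
    x0 = float(tiepoint[3])
    top = float(tiepoint[4])
    grid = GridSpec((x0, top - n_rows * cell), n_rows, n_cols, cell)
    return Raster(grid, np.flipud(data).copy(), name=name)
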