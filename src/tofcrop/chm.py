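"""Raster height models: DSM, DTM and crop height model (CHM = DSM - DTM).

Height models are derived directly from a single-campaign point cloud:
the digital surface model takes the *maximum* elevation of the points in
each cell, the digital terrain model the *minimum* — no interpolation,
so a cell's CHM value is trustworthy exactly when both the canopy top
and the bare ground were actually sampled inside it.  The default cell
size of 0.25 m is matched to maize plant spacing: fine enough for a
seamless model, coarse enough to avoid several plant tips per cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import DomainError, PointCloud

__all__ = [
    "RasterGrid",
    "CHMSet",
    "grid_definition_for_aoi",
    "rasterize_extreme",
    "derive_chm",
    "trim_border",
    "difference_raster",
    "build_chm_set",
]

NODATA = -9999.0


@dataclass
class RasterGrid:
    """Regular 2D grid of elevations/heights in metres.

    ``origin`` is the lower-left (south-west) corner; ``values`` is
    stored north-up, i.e. row 0 is the *northernmost* row, matching the
    ESRI ASCII grid serialisation.  Nodata cells hold NaN internally.

    Cells are half-open: ``[x0 + i*s, x0 + (i+1)*s)``; a point exactly
    on the grid's max edge is assigned to the last cell so every point
    inside the closed AOI maps to exactly one cell.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise DomainError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("raster values must be a 2D array")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.cell_size, other.cell_size, rel_tol=0, abs_tol=1e-12)
            and math.isclose(self.origin[0], other.origin[0], rel_tol=0, abs_tol=1e-9)
            and math.isclose(self.origin[1], other.origin[1], rel_tol=0, abs_tol=1e-9)
        )

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.origin, self.cell_size, self.values.copy())

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices for coordinates; max-edge points clamp to last cell."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row_s = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size).astype(int)
        col = np.where(
            np.isclose(np.asarray(x), self.origin[0] + self.n_cols * self.cell_size),
            self.n_cols - 1,
            col,
        )
        row_s = np.where(
            np.isclose(np.asarray(y), self.origin[1] + self.n_rows * self.cell_size),
            self.n_rows - 1,
            row_s,
        )
        return self.n_rows - 1 - row_s, col


@dataclass
class CHMSet:
    """Aligned DSM, DTM and CHM rasters of one point cloud."""

    dsm: RasterGrid
    dtm: RasterGrid
    chm: RasterGrid


def grid_definition_for_aoi(
    xmin: float, ymin: float, xmax: float, ymax: float, cell_size: float
) -> tuple[tuple[float, float], tuple[int, int]]:
    """Grid origin and (n_rows, n_cols) covering the AOI at the cell size."""
    if not (xmin < xmax and ymin < ymax):
        raise DomainError("inverted AOI bounds")
    n_cols = max(1, int(math.ceil((xmax - xmin) / cell_size - 1e-9)))
    n_rows = max(1, int(math.ceil((ymax - ymin) / cell_size - 1e-9)))
    return (xmin, ymin), (n_rows, n_cols)


def rasterize_extreme(
    cloud: PointCloud,
    origin: tuple[float, float],
    cell_size: float,
    shape: tuple[int, int],
    mode: str = "max",
) -> RasterGrid:
    """Per-cell extreme elevation raster (``mode='max'`` DSM, ``'min'`` DTM).

    Cells containing no points are nodata.  Points outside the grid
    extent are ignored.
    """
    if mode not in ("max", "min"):
        raise DomainError("mode must be 'max' or 'min'")
    grid = RasterGrid(origin, cell_size, np.full(shape, np.nan))
    if len(cloud) == 0:
        warnings.warn("rasterizing an empty cloud: all cells are nodata", stacklevel=2)
        return grid
    row, col = grid.cell_index(cloud.x, cloud.y)
    ok = (row >= 0) & (row < shape[0]) & (col >= 0) & (col < shape[1])
    row, col, z = row[ok], col[ok], cloud.z[ok]
    flat = row * shape[1] + col
    if mode == "max":
        acc = np.full(shape[0] * shape[1], -np.inf)
        np.maximum.at(acc, flat, z)
    else:
        acc = np.full(shape[0] * shape[1], np.inf)
        np.minimum.at(acc, flat, z)
    acc[~np.isfinite(acc)] = np.nan
    grid.values = acc.reshape(shape)
    return grid


def derive_chm(dsm: RasterGrid, dtm: RasterGrid) -> RasterGrid:
    """Crop height model: cellwise DSM - DTM; nodata propagates."""
    if not dsm.aligned_with(dtm):
        raise DomainError("DSM and DTM grids are not aligned")
    return RasterGrid(dsm.origin, dsm.cell_size, dsm.values - dtm.values)


def trim_border(grid: RasterGrid, rings: int = 1) -> RasterGrid:
    """Mask the outermost ring(s) of cells as nodata.

    Border cells are typically only partly covered by the point clouds,
    so their extremes are unreliable; masking (rather than shrinking)
    keeps all rasters co-registered.
    """
    if rings < 1:
        raise DomainError("rings must be >= 1")
    if grid.n_rows <= 2 * rings or grid.n_cols <= 2 * rings:
        raise DomainError(
            f"grid {grid.n_rows}x{grid.n_cols} too small to trim {rings} ring(s)"
        )
    out = grid.copy()
    out.values[:rings, :] = np.nan
    out.values[-rings:, :] = np.nan
    out.values[:, :rings] = np.nan
    out.values[:, -rings:] = np.nan
    return out


def difference_raster(test: RasterGrid, reference: RasterGrid) -> RasterGrid:
    """Cellwise test - reference (positive where the test model is higher)."""
    if not test.aligned_with(reference):
        raise DomainError("difference_raster requires aligned grids")
    return RasterGrid(test.origin, test.cell_size, test.values - reference.values)


def build_chm_set(
    cloud: PointCloud,
    origin: tuple[float, float],
    cell_size: float,
    shape: tuple[int, int],
    trim_rings: int = 1,
) -> CHMSet:
    """DSM, DTM and border-trimmed CHM of one pre-processed cloud."""
    dsm = rasterize_extreme(cloud, origin, cell_size, shape, mode="max")
    dtm = rasterize_extreme(cloud, origin, cell_size, shape, mode="min")
    chm = derive_chm(dsm, dtm)
    if trim_rings:
        chm = trim_border(chm, trim_rings)
    return CHMSet(dsm=dsm, dtm=dtm, chm=chm)
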