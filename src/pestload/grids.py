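"""Planar gridded layers: categorical crop rasters and population-count grids.

Both layers live in one shared projected coordinate frame in meters, row-major
and north-up with the origin at the *top-left corner* of the grid: column
index grows eastward (+x), row index grows southward (-y). Cell (row, col) is
therefore centred at

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size

Population layers carry person *counts* per cell, not densities, so summing
cells gives populations directly and no pixel-area correction is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class _GridLayer:
    origin: tuple[float, float]  # (x, y) of the top-left corner, meters
    cell_size_m: float

    def __post_init__(self):
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        self.cell_size_m = float(self.cell_size_m)
        if self.cell_size_m <= 0:
            raise ValueError(f"cell_size_m must be > 0, got {self.cell_size_m}")

    @property
    def n_rows(self) -> int:
        return self._array().shape[0]

    @property
    def n_cols(self) -> int:
        return self._array().shape[1]

    def _array(self) -> np.ndarray:  # pragma: no cover - overridden
        raise NotImplementedError

    def col_centers_x(self) -> np.ndarray:
        """x coordinate of every column's cell centers."""
        return self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size_m

    def row_centers_y(self) -> np.ndarray:
        """y coordinate of every row's cell centers (decreasing southward)."""
        return self.origin[1] - (np.arange(self.n_rows) + 0.5) * self.cell_size_m

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_m**2 / 1e6


@dataclass
class CropRaster(_GridLayer):
    """Categorical crop-cover raster (e.g. a cropland data layer excerpt).

    ``crop_codes`` is the set of integer category codes counted as the target
    crop; everything else is background.
    """

    values: np.ndarray = None
    crop_codes: frozenset[int] = frozenset({5})  # CDL code 5 = soybeans

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D grid")
        self.crop_codes = frozenset(int(c) for c in self.crop_codes)
        if not self.crop_codes:
            raise ValueError("crop_codes must be non-empty")

    def _array(self) -> np.ndarray:
        return self.values

    def crop_mask(self) -> np.ndarray:
        """Boolean grid: True where the cell is coded as the target crop."""
        return np.isin(self.values, sorted(self.crop_codes))


@dataclass
class PopulationGrid(_GridLayer):
    """Gridded population counts (persons per cell), nominally 1000 m cells."""

    counts: np.ndarray = None

    def __post_init__(self):
        super().__post_init__()
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 2-D grid")
        if np.any(self.counts < 0):
            raise ValueError("population counts must be non-negative")

    def _array(self) -> np.ndarray:
        return self.counts

    @property
    def total_population(self) -> float:
        return float(self.counts.sum())

    def populated_cells(self) -> list[tuple[int, int]]:
        """(row, col) of every cell with count > 0, row-major order."""
        rows, cols = np.nonzero(self.counts > 0)
        return list(zip(rows.tolist(), cols.tolist()))


def cell_center(grid: _GridLayer, row: int, col: int) -> tuple[float, float]:
    """Planar (x, y) of a cell center; raises ``IndexError`` out of range."""
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise IndexError(f"cell ({row}, {col}) outside grid {grid.n_rows}x{grid.n_cols}")
    return (
        grid.origin[0] + (col + 0.5) * grid.cell_size_m,
        grid.origin[1] - (row + 0.5) * grid.cell_size_m,
    )
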