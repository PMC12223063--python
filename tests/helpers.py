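"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: plain Python loops,
hand-written order-statistic interpolation, and full-grid meshes instead of
windowed extraction.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import Point


def disc_area_loop_km2(raster, center, radius_m):
    """Pure-Python per-cell distance check (for small rasters)."""
    cx, cy = center
    total_cells = 0
    for row in range(raster.values.shape[0]):
        y = raster.origin[1] - (row + 0.5) * raster.cell_size_m
        for col in range(raster.values.shape[1]):
            if int(raster.values[row, col]) not in raster.crop_codes:
                continue
            x = raster.origin[0] + (col + 0.5) * raster.cell_size_m
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius_m**2:
                total_cells += 1
    cell_area_km2 = raster.cell_size_m**2 / 1e6
    return total_cells * cell_area_km2


def disc_area_grid_km2(raster, center, radius_m):
    """Exhaustive full-grid mesh oracle (every cell tested, vectorized)."""
    cx, cy = center
    nr, nc = raster.values.shape
    xs = raster.origin[0] + (np.arange(nc) + 0.5) * raster.cell_size_m
    ys = raster.origin[1] - (np.arange(nr) + 0.5) * raster.cell_size_m
    xx, yy = np.meshgrid(xs, ys)
    within = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_m**2
    crop = np.isin(raster.values, sorted(raster.crop_codes))
    cell_area_km2 = raster.cell_size_m**2 / 1e6
    return int(np.count_nonzero(within & crop)) * cell_area_km2


def polygon_area_loop_km2(raster, polygon):
    """Per-cell point-in-polygon loop for county crop areas."""
    cells = 0
    for row in range(raster.values.shape[0]):
        y = raster.origin[1] - (row + 0.5) * raster.cell_size_m
        for col in range(raster.values.shape[1]):
            if int(raster.values[row, col]) not in raster.crop_codes:
                continue
            x = raster.origin[0] + (col + 0.5) * raster.cell_size_m
            if polygon.contains(Point(x, y)):
                cells += 1
    cell_area_km2 = raster.cell_size_m**2 / 1e6
    return cells * cell_area_km2


def quantile_interp(values, q):
    """Linear interpolation of order statistics, written out by hand."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def classify_oracle(values, n_classes=3):
    """Rank-based classification oracle: count breaks strictly below."""
    breaks = [quantile_interp(values, i / n_classes) for i in range(1, n_classes)]
    return [1 + sum(v > b for b in breaks) for v in values]


def summary_oracle(pcts):
    """Sort-and-index median/mean/min/max."""
    s = sorted(pcts)
    n = len(s)
    median = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0
    return {
        "median": median,
        "mean": sum(s) / n,
        "min": s[0],
        "max": s[-1],
    }
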