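"""County-level load estimation and temporal percent-change analysis.

County load is the state application density allocated to each county by its
planted crop area:

    W_C = A_C * D_P      [kg]

Temporal trends are per-county percent changes 100*(end-start)/start of load
and of planted area between a start and an end year, summarised across
counties by median/mean/min/max. Counties whose end-year planted area falls
below a small-area threshold (default 40.5 km^2 = 10,000 acres) are flagged
but *not* excluded from the summary statistics.

Where a survey area is unavailable the county's crop area can be measured
from a categorical crop raster instead (``raster_county_area``); such areas
carry ``source="raster_fallback"`` for provenance.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely

from .errors import ConsistencyError, PestloadError
from .grids import CropRaster
from .units import ApplicationDensity, AreaUnit, convert_area

logger = logging.getLogger(__name__)

#: Fig.-style small-area cutoff: 40.5 km^2, i.e. 10,000 acres.
SMALL_AREA_KM2 = 40.5


@dataclass(frozen=True)
class CountyCropArea:
    county_id: str
    year: int
    area: float
    unit: AreaUnit = AreaUnit.KM2
    source: str = "survey"  # or "raster_fallback"

    def __post_init__(self):
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")
        if self.source not in ("survey", "raster_fallback"):
            raise ValueError(f"unknown area source: {self.source!r}")

    @property
    def area_km2(self) -> float:
        return convert_area(self.area, self.unit, AreaUnit.KM2)


@dataclass(frozen=True)
class CountyLoad:
    county_id: str
    year: int
    load_kg: float

    def __post_init__(self):
        if self.load_kg < 0:
            raise ValueError(f"load must be >= 0, got {self.load_kg}")


@dataclass(frozen=True)
class CountyTrendRecord:
    county_id: str
    load_start_kg: float
    load_end_kg: float
    load_pct_change: float  # NaN when undefined
    area_start_km2: float
    area_end_km2: float
    area_pct_change: float  # NaN when undefined
    small_area_flag: bool
    pct_change_defined: bool


@dataclass(frozen=True)
class TrendSummary:
    median_pct: float
    mean_pct: float
    min_pct: float
    max_pct: float
    n_counties: int


def county_load(area: CountyCropArea, density: ApplicationDensity) -> CountyLoad:
    """W_C = A_C (km^2) * D_P (kg/km^2)."""
    if area.year != density.year:
        raise ConsistencyError(f"area year {area.year} != density year {density.year}")
    return CountyLoad(
        county_id=area.county_id,
        year=area.year,
        load_kg=area.area_km2 * density.density_kg_per_km2,
    )


def percent_change(v_start: float, v_end: float) -> float:
    """100 * (v_end - v_start) / v_start; NaN (with a warning) on zero baseline.

    The sign is preserved for decreases. A non-positive baseline makes the
    rate undefined rather than infinite; callers record the NaN through
    ``pct_change_defined``.
    """
    if v_start <= 0:
        logger.warning("percent change undefined for baseline %s", v_start)
        return math.nan
    return 100.0 * (v_end - v_start) / v_start


def flag_small_area(area: "CountyCropArea | float", threshold_km2: float = SMALL_AREA_KM2) -> bool:
    """True iff the area (km^2) is strictly below the threshold."""
    km2 = area.area_km2 if isinstance(area, CountyCropArea) else float(area)
    if km2 < 0:
        raise ValueError(f"area must be >= 0, got {km2}")
    return km2 < threshold_km2


def build_trend_records(
    start_areas: Sequence[CountyCropArea],
    end_areas: Sequence[CountyCropArea],
    start_density: ApplicationDensity,
    end_density: ApplicationDensity,
    small_area_threshold_km2: float = SMALL_AREA_KM2,
) -> list[CountyTrendRecord]:
    """Compute per-county loads for both years and their percent changes.

    Counties must appear in both years; output preserves the start-year order.
    """
    end_by_id = {a.county_id: a for a in end_areas}
    missing = [a.county_id for a in start_areas if a.county_id not in end_by_id]
    if missing:
        raise ConsistencyError(f"counties missing from end year: {missing}")
    records = []
    for a0 in start_areas:
        a1 = end_by_id[a0.county_id]
        w0 = county_load(a0, start_density).load_kg
        w1 = county_load(a1, end_density).load_kg
        records.append(
            trend_record_from_values(
                a0.county_id, w0, w1, a0.area_km2, a1.area_km2, small_area_threshold_km2
            )
        )
    return records


def trend_record_from_values(
    county_id: str,
    load_start_kg: float,
    load_end_kg: float,
    area_start_km2: float,
    area_end_km2: float,
    small_area_threshold_km2: float = SMALL_AREA_KM2,
) -> CountyTrendRecord:
    """Assemble one trend record from already-known loads and areas."""
    load_pct = percent_change(load_start_kg, load_end_kg)
    area_pct = percent_change(area_start_km2, area_end_km2)
    return CountyTrendRecord(
        county_id=county_id,
        load_start_kg=load_start_kg,
        load_end_kg=load_end_kg,
        load_pct_change=load_pct,
        area_start_km2=area_start_km2,
        area_end_km2=area_end_km2,
        area_pct_change=area_pct,
        small_area_flag=flag_small_area(area_end_km2, small_area_threshold_km2),
        pct_change_defined=not math.isnan(load_pct),
    )


def trend_summary(records: Iterable[CountyTrendRecord]) -> TrendSummary:
    """Median/mean/min/max of the defined load percent changes.

    Median for an even count is the midpoint of the two central order
    statistics; all counties with a defined change contribute, including
    small-area-flagged ones.
    """
    pcts = [r.load_pct_change for r in records if r.pct_change_defined]
    if not pcts:
        raise PestloadError("no records with a defined percent change")
    return TrendSummary(
        median_pct=float(statistics.median(pcts)),
        mean_pct=float(sum(pcts) / len(pcts)),
        min_pct=float(min(pcts)),
        max_pct=float(max(pcts)),
        n_counties=len(pcts),
    )


def raster_county_area(crop_raster: CropRaster, county_polygon) -> float:
    """Crop area (km^2) inside a county, from the crop raster.

    Counts crop-coded cells whose *centers* fall strictly inside the polygon
    (no fractional boundary cells): deterministic and exactly reproducible by
    per-cell point-in-polygon iteration. Disjoint extents return 0 with a
    warning.
    """
    minx, miny, maxx, maxy = county_polygon.bounds
    xs = crop_raster.col_centers_x()
    ys = crop_raster.row_centers_y()
    col_sel = np.nonzero((xs >= minx) & (xs <= maxx))[0]
    row_sel = np.nonzero((ys >= miny) & (ys <= maxy))[0]
    if col_sel.size == 0 or row_sel.size == 0:
        logger.warning("county polygon %s disjoint from crop raster extent", county_polygon.bounds)
        return 0.0
    sub = crop_raster.crop_mask()[np.ix_(row_sel, col_sel)]
    if not sub.any():
        return 0.0
    rr, cc = np.nonzero(sub)
    pts = shapely.points(xs[col_sel][cc], ys[row_sel][rr])
    inside = shapely.contains(county_polygon, pts)
    return float(inside.sum()) * crop_raster.cell_area_km2
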