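"""End-to-end driver: density -> county trends -> bivariate -> buffer exposure.

Stages run in order for the configured years and are skipped (with a log
line) when their inputs are not configured. The driver adds no arithmetic of
its own: every number in the JSON summary comes from a module operation, so
two runs on identical inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import shapely

from . import io as pio
from .bivariate import CountyDensityPair, counties_of_concern
from .config import PipelineConfig
from .errors import ConsistencyError, PestloadError
from .exposure import (
    BufferSpec,
    ExposureThresholds,
    classify_exposure,
    compute_buffer_records,
    exposure_change,
    exposure_summary,
)
from .grids import PopulationGrid
from .trends import build_trend_records, raster_county_area, trend_summary
from .units import densities_by_year

logger = logging.getLogger(__name__)


def county_population(pop: PopulationGrid, polygon) -> float:
    """Population inside a county: cells whose centers the polygon contains."""
    xs = pop.col_centers_x()
    ys = pop.row_centers_y()
    rr, cc = np.nonzero(pop.counts > 0)
    if rr.size == 0:
        return 0.0
    pts = shapely.points(xs[cc], ys[rr])
    inside = shapely.contains(polygon, pts)
    return float(pop.counts[rr[inside], cc[inside]].sum())


def _clean(value):
    """NaN -> None recursively, for strict-JSON summaries."""
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, dict):
        return {k: _clean(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_clean(v) for v in value]
    return value


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the JSON summary."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    years = sorted(config.years)
    start_year = config.start_year if config.start_year is not None else years[0]
    end_year = config.end_year if config.end_year is not None else years[-1]

    summary: dict = {"years": years}

    # ---- application density --------------------------------------------
    if not (config.use_csv and config.state_area_csv):
        raise PestloadError("density stage requires use_csv and state_area_csv")
    uses = [u for u in pio.read_use_csv(config.use_csv) if u.year in years]
    totals = [t for t in pio.read_state_area_csv(config.state_area_csv) if t.year in years]
    missing = set(years) - {u.year for u in uses}
    if missing:
        raise ConsistencyError(f"use table missing configured years: {sorted(missing)}")
    densities = densities_by_year(uses, totals)
    summary["densities"] = {
        str(y): {
            "kg_per_km2": d.density_kg_per_km2,
            "kg_per_km2_2dp": d.rounded(2),
        }
        for y, d in sorted(densities.items())
    }
    logger.info("density stage: %d year(s)", len(densities))

    # ---- county trends ---------------------------------------------------
    trend_records = None
    if config.county_area_csv:
        areas = pio.read_county_area_csv(config.county_area_csv)
        start_areas = [a for a in areas if a.year == start_year]
        end_areas = [a for a in areas if a.year == end_year]
        if not start_areas or not end_areas:
            raise ConsistencyError(
                f"county area table lacks start/end years {start_year}/{end_year}"
            )
        trend_records = build_trend_records(
            start_areas, end_areas, densities[start_year], densities[end_year],
            small_area_threshold_km2=config.small_area_km2,
        )
        pio.write_trend_csv(out_dir / "county_trends.csv", trend_records)
        ts = trend_summary(trend_records)
        summary["trend_summary"] = {
            "median_pct": ts.median_pct,
            "mean_pct": ts.mean_pct,
            "min_pct": ts.min_pct,
            "max_pct": ts.max_pct,
            "n_counties": ts.n_counties,
            "total_increase_kg": sum(r.load_end_kg - r.load_start_kg for r in trend_records),
        }
        logger.info("trend stage: %d counties", len(trend_records))
    else:
        logger.info("trend stage skipped (no county_area_csv)")

    # ---- bivariate screening --------------------------------------------
    if config.counties_geojson and config.population_geotiff:
        counties = pio.read_counties_geojson(config.counties_geojson)
        pop = pio.read_population_geotiff(config.population_geotiff)
        bi_year = config.bivariate_year if config.bivariate_year is not None else end_year
        load_by_county = {}
        if trend_records is not None:
            key = "load_end_kg" if bi_year == end_year else "load_start_kg"
            load_by_county = {r.county_id: getattr(r, key) for r in trend_records}
        crop = (
            pio.read_crop_geotiff(config.crop_geotiff, config.crop_codes)
            if config.crop_geotiff
            else None
        )
        pairs = []
        for cid, poly in counties:
            if cid in load_by_county:
                load = load_by_county[cid]
            elif crop is not None:  # raster-fallback county crop area
                load = raster_county_area(crop, poly) * densities[bi_year].density_kg_per_km2
            else:
                raise PestloadError(
                    f"no load source for county {cid!r}: provide county_area_csv or crop_geotiff"
                )
            pairs.append(
                CountyDensityPair(
                    county_id=cid,
                    population=county_population(pop, poly),
                    county_area_km2=poly.area / 1e6,
                    load_kg=load,
                )
            )
        classes = counties_of_concern(
            pairs, n_classes=config.bivariate_n_classes, method=config.bivariate_break_method
        )
        pio.write_bivariate_csv(out_dir / "bivariate.csv", pairs, classes)
        summary["counties_of_concern"] = [c.county_id for c in classes if c.concern]
        logger.info(
            "bivariate stage: %d counties, %d of concern",
            len(pairs), len(summary["counties_of_concern"]),
        )
    else:
        logger.info("bivariate stage skipped (needs counties_geojson + population_geotiff)")

    # ---- buffer exposure -------------------------------------------------
    if config.crop_geotiff and config.population_geotiff:
        crop = pio.read_crop_geotiff(config.crop_geotiff, config.crop_codes)
        pop = pio.read_population_geotiff(config.population_geotiff)
        thresholds = ExposureThresholds(
            proximity_min_crop_km2=config.proximity_km2,
            dust_threshold_kg=config.dust_kg,
            reference_kg=config.reference_kg,
        )
        spec = BufferSpec(core_radius_m=250.0, donut_width_m=config.buffer_radius_m - 250.0)
        summaries_by_year: dict[int, dict] = {}
        summary["exposure"] = {}
        for year in years:
            records = compute_buffer_records(
                pop, crop, densities[year], spec,
                include_unpopulated=config.include_unpopulated,
            )
            flags = classify_exposure(records, thresholds)
            pio.write_exposure_cells_csv(out_dir / f"exposure_cells_{year}.csv", records, flags)
            summaries_by_year[year] = {
                rule: exposure_summary(pop, records, flags, rule, thresholds)
                for rule in ExposureThresholds.RULES
            }
            summary["exposure"][str(year)] = {
                rule: {
                    "threshold": s.threshold,
                    "exposed_population": s.exposed_population,
                    "exposed_fraction_pct": s.exposed_fraction_pct,
                    "n_cells_exposed": s.n_cells_exposed,
                }
                for rule, s in summaries_by_year[year].items()
            }
            logger.info("exposure stage %d: %d receptor cells", year, len(records))
        pio.write_exposure_summary_csv(
            out_dir / "exposure_summary.csv",
            [s for y in years for s in summaries_by_year[y].values()],
        )
        if start_year != end_year:
            summary["exposure_change"] = {}
            for rule in ExposureThresholds.RULES:
                ch = exposure_change(
                    summaries_by_year[start_year][rule], summaries_by_year[end_year][rule]
                )
                summary["exposure_change"][rule] = {
                    "population_change": ch.population_change,
                    "population_pct_change": ch.population_pct_change,
                    "fraction_change_pct_points": ch.fraction_change_pct_points,
                    "pct_change_defined": ch.pct_change_defined,
                }
    else:
        logger.info("exposure stage skipped (needs crop_geotiff + population_geotiff)")

    summary = _clean(summary)
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    return summary
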