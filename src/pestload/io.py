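"""Readers and writers for the pipeline's standard formats.

CSV schemas (UTF-8, header row, period decimal separator; thousands
separators and stray whitespace in numeric fields are stripped on ingest):

* use tables:      ``year, region, formulation, kg``
* crop-area tables: ``year, region, area, unit`` (+ optional ``source``)

Rasters travel as single-band GeoTIFFs in a planar meter frame; the
georeferencing read and written here is the GeoTIFF ModelPixelScale /
ModelTiepoint tag pair (top-left anchored, north-up). Nodata (GDAL_NODATA
tag) in population rasters is treated as zero population with a logged
count. County polygons travel as a GeoJSON FeatureCollection with a
``county_id`` property per feature.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

from .errors import PestloadError
from .grids import CropRaster, PopulationGrid
from .trends import CountyCropArea, CountyTrendRecord
from .units import AreaUnit, PesticideUseRecord, StateCropTotal

logger = logging.getLogger(__name__)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113


def _num(raw: str, path, row_no: int, field: str) -> float:
    try:
        return float(str(raw).strip().replace(",", ""))
    except (TypeError, ValueError):
        raise PestloadError(f"{path}: row {row_no}: bad numeric field {field!r}: {raw!r}") from None


def _read_rows(path, required: Sequence[str]) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(required) <= set(reader.fieldnames):
            raise PestloadError(
                f"{path}: header must contain {list(required)}, got {reader.fieldnames}"
            )
        return list(reader)


def read_use_csv(path) -> list[PesticideUseRecord]:
    """Use table -> one record per (year, region), formulations collected."""
    grouped: dict[tuple[int, str], list[float]] = {}
    for i, row in enumerate(_read_rows(path, ("year", "region", "formulation", "kg")), start=2):
        year = int(_num(row["year"], path, i, "year"))
        key = (year, row["region"].strip())
        grouped.setdefault(key, []).append(_num(row["kg"], path, i, "kg"))
    return [
        PesticideUseRecord(year=year, formulation_kg=tuple(kgs), region_label=region)
        for (year, region), kgs in sorted(grouped.items())
    ]


def read_state_area_csv(path) -> list[StateCropTotal]:
    out = []
    for i, row in enumerate(_read_rows(path, ("year", "region", "area", "unit")), start=2):
        out.append(
            StateCropTotal(
                year=int(_num(row["year"], path, i, "year")),
                area=_num(row["area"], path, i, "area"),
                unit=AreaUnit(row["unit"].strip()),
            )
        )
    return out


def read_county_area_csv(path) -> list[CountyCropArea]:
    out = []
    for i, row in enumerate(_read_rows(path, ("year", "region", "area", "unit")), start=2):
        out.append(
            CountyCropArea(
                county_id=row["region"].strip(),
                year=int(_num(row["year"], path, i, "year")),
                area=_num(row["area"], path, i, "area"),
                unit=AreaUnit(row["unit"].strip()),
                source=(row.get("source") or "survey").strip(),
            )
        )
    return out


# ---------------------------------------------------------------- GeoTIFF

def write_geotiff(path, array: np.ndarray, origin: tuple[float, float],
                  cell_size_m: float, nodata: "float | None" = None) -> None:
    """Single-band GeoTIFF with pixel-scale/tiepoint georeferencing."""
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(cell_size_m), float(cell_size_m), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)),
    ]
    if nodata is not None:
        extratags.append((_TAG_NODATA, "s", 0, str(nodata)))
    tifffile.imwrite(path, np.asarray(array), extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, tuple[float, float], float, "float | None"]:
    """Return (array, origin, cell_size_m, nodata) from a single-band GeoTIFF."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        array = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise PestloadError(f"{path}: missing GeoTIFF pixel-scale/tiepoint tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if abs(sx - sy) > 1e-9:
            raise PestloadError(f"{path}: anisotropic pixels ({sx} x {sy}) unsupported")
        tie = tags[_TAG_TIEPOINT].value
        # raster point (tie[0], tie[1]) maps to model (tie[3], tie[4])
        origin = (float(tie[3]) - float(tie[0]) * sx, float(tie[4]) + float(tie[1]) * sy)
        nodata = None
        if _TAG_NODATA in tags:
            nodata = float(tags[_TAG_NODATA].value)
    return array, origin, float(sx), nodata


def read_crop_geotiff(path, crop_codes: Iterable[int] = (5,)) -> CropRaster:
    array, origin, cell, _ = read_geotiff(path)
    return CropRaster(origin=origin, cell_size_m=cell, values=array,
                      crop_codes=frozenset(crop_codes))


def read_population_geotiff(path) -> PopulationGrid:
    array, origin, cell, nodata = read_geotiff(path)
    counts = np.asarray(array, dtype=float)
    bad = ~np.isfinite(counts)
    if nodata is not None:
        bad |= counts == nodata
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: %d nodata/non-finite population cells set to 0", path, n_bad)
        counts = np.where(bad, 0.0, counts)
    return PopulationGrid(origin=origin, cell_size_m=cell, counts=counts)


# ---------------------------------------------------------------- GeoJSON

def write_counties_geojson(path, counties: Sequence[tuple[str, object]]) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"county_id": cid},
            "geometry": mapping(poly),
        }
        for cid, poly in counties
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_counties_geojson(path) -> list[tuple[str, object]]:
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise PestloadError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        if "county_id" not in props:
            raise PestloadError(f"{path}: feature without county_id property")
        out.append((str(props["county_id"]), shape(feat["geometry"])))
    return out


# ---------------------------------------------------------------- writers

def _fmt(x: float) -> str:
    return repr(float(x))  # full round-trip precision


def write_trend_csv(path, records: Sequence[CountyTrendRecord]) -> None:
    """Trend table mirroring the published change-table columns.

    Full-precision columns plus presentation-rounded percent columns (1 dp).
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([
            "county", "load_start_kg", "load_end_kg", "load_pct_change",
            "area_start_km2", "area_end_km2", "area_pct_change",
            "small_area_flag", "pct_change_defined",
            "load_pct_change_1dp", "area_pct_change_1dp",
        ])
        for r in records:
            w.writerow([
                r.county_id, _fmt(r.load_start_kg), _fmt(r.load_end_kg),
                _fmt(r.load_pct_change), _fmt(r.area_start_km2), _fmt(r.area_end_km2),
                _fmt(r.area_pct_change), r.small_area_flag, r.pct_change_defined,
                round(r.load_pct_change, 1), round(r.area_pct_change, 1),
            ])


def write_bivariate_csv(path, pairs, classes) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["county", "population", "county_area_km2", "pop_density",
                    "pest_density", "pop_class", "pest_class", "concern"])
        for p, c in zip(pairs, classes):
            w.writerow([p.county_id, _fmt(p.population), _fmt(p.county_area_km2),
                        _fmt(p.pop_density), _fmt(p.pesticide_density),
                        c.pop_class, c.pest_class, c.concern])


def write_exposure_cells_csv(path, records, flags) -> None:
    flag_by_cell = {f.cell_id: f for f in flags}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["row", "col", "x", "y", "population", "crop_area_km2",
                    "load_kg", "proximity", "dust", "reference"])
        for r in records:
            f = flag_by_cell[r.cell_id]
            w.writerow([r.cell_id[0], r.cell_id[1], _fmt(r.center[0]), _fmt(r.center[1]),
                        _fmt(r.population), _fmt(r.crop_area_km2), _fmt(r.load_kg),
                        f.proximity, f.dust, f.reference])


def write_exposure_summary_csv(path, summaries) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "rule", "threshold", "exposed_population",
                    "exposed_fraction_pct", "n_cells_exposed", "total_population"])
        for s in summaries:
            w.writerow([s.year, s.rule, _fmt(s.threshold), _fmt(s.exposed_population),
                        _fmt(s.exposed_fraction_pct), s.n_cells_exposed,
                        _fmt(s.total_population)])


def write_manifest(path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
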