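"""Bundled published tables for the Illinois soybean 2,4-D case study.

Two small CSVs ship with the package:

* ``illinois_soy_24d_state.csv`` — state-level soybean area planted (km^2)
  and 2,4-D applied (kg of active ingredient) for 2017, 2020 and 2023, from
  the USDA-NASS agricultural survey / chemical use program.
* ``illinois_soy_24d_county.csv`` — the published 102-county change table:
  2,4-D applied to soybeans (kg) and soybean acres planted in 2017 and 2023,
  with the published percent changes.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .trends import CountyTrendRecord, trend_record_from_values
from .units import ApplicationDensity, PesticideUseRecord, StateCropTotal, acres_to_km2


def _data_path(name: str):
    return files("pestload").joinpath("data", name)


def load_state_use() -> pd.DataFrame:
    """Columns: year, region, soybean_area_km2, use_kg."""
    with _data_path("illinois_soy_24d_state.csv").open() as fh:
        return pd.read_csv(fh)


def load_county_change() -> pd.DataFrame:
    """The 102-county published change table (kg and acres, 2017 vs 2023)."""
    with _data_path("illinois_soy_24d_county.csv").open() as fh:
        return pd.read_csv(fh)


def state_records() -> tuple[list[PesticideUseRecord], list[StateCropTotal]]:
    df = load_state_use()
    uses = [
        PesticideUseRecord(year=int(r.year), formulation_kg=(float(r.use_kg),),
                           region_label=str(r.region))
        for r in df.itertuples()
    ]
    totals = [
        StateCropTotal(year=int(r.year), area=float(r.soybean_area_km2))
        for r in df.itertuples()
    ]
    return uses, totals


def state_densities() -> dict[int, ApplicationDensity]:
    """Application density D_P per study year from the bundled state table."""
    from .units import densities_by_year

    uses, totals = state_records()
    return densities_by_year(uses, totals)


def county_trend_records() -> list[CountyTrendRecord]:
    """Trend records built from the published county kg and acre columns."""
    df = load_county_change()
    return [
        trend_record_from_values(
            county_id=str(r.county),
            load_start_kg=float(r.use_kg_2017),
            load_end_kg=float(r.use_kg_2023),
            area_start_km2=acres_to_km2(float(r.acres_2017)),
            area_end_km2=acres_to_km2(float(r.acres_2023)),
        )
        for r in df.itertuples()
    ]
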