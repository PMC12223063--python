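"""Pipeline configuration: YAML file + programmatic overrides.

Precedence is CLI flags > config file > defaults. Only keys that are set in
the YAML override the dataclass defaults; unknown keys are rejected early.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import PestloadError


@dataclass
class PipelineConfig:
    # inputs
    use_csv: "str | None" = None
    state_area_csv: "str | None" = None
    county_area_csv: "str | None" = None
    crop_geotiff: "str | None" = None
    population_geotiff: "str | None" = None
    counties_geojson: "str | None" = None
    # analysis settings
    years: tuple[int, ...] = ()
    start_year: "int | None" = None
    end_year: "int | None" = None
    buffer_radius_m: float = 1000.0
    proximity_km2: float = 0.04
    dust_kg: float = 4.4
    reference_kg: float = 30.0
    crop_codes: tuple[int, ...] = (5,)
    small_area_km2: float = 40.5
    bivariate_n_classes: int = 3
    bivariate_break_method: str = "quantile"
    bivariate_year: "int | None" = None
    include_unpopulated: bool = False
    # output
    out_dir: str = "pestload_out"
    verbose: bool = False

    _FLAT_KEYS = None  # populated below

    def validate(self, require_inputs: bool = True) -> None:
        if not self.years:
            raise PestloadError("config error: 'years' must be a non-empty list")
        if min(self.proximity_km2, self.dust_kg, self.reference_kg, self.buffer_radius_m) <= 0:
            raise PestloadError("config error: thresholds and buffer radius must be positive")
        if require_inputs:
            for name in ("use_csv", "state_area_csv", "county_area_csv",
                         "crop_geotiff", "population_geotiff", "counties_geojson"):
                path = getattr(self, name)
                if path is not None and not Path(path).exists():
                    raise PestloadError(f"config error: {name} does not exist: {path}")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


# nested YAML key -> dataclass field
_NESTED = {
    ("inputs", "use_csv"): "use_csv",
    ("inputs", "state_area_csv"): "state_area_csv",
    ("inputs", "county_area_csv"): "county_area_csv",
    ("inputs", "crop_geotiff"): "crop_geotiff",
    ("inputs", "population_geotiff"): "population_geotiff",
    ("inputs", "counties_geojson"): "counties_geojson",
    ("buffer", "radius_m"): "buffer_radius_m",
    ("thresholds", "proximity_km2"): "proximity_km2",
    ("thresholds", "dust_kg"): "dust_kg",
    ("thresholds", "reference_kg"): "reference_kg",
    ("crop", "codes"): "crop_codes",
    ("bivariate", "n_classes"): "bivariate_n_classes",
    ("bivariate", "break_method"): "bivariate_break_method",
    ("bivariate", "year"): "bivariate_year",
}
_TOP = {"years", "start_year", "end_year", "small_area_km2", "out_dir",
        "verbose", "include_unpopulated"}


def load_config(path) -> PipelineConfig:
    """Read a YAML config; unknown keys are an error."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in raw.items():
        if key in _TOP:
            kwargs[key] = tuple(value) if key == "years" else value
        elif isinstance(value, dict):
            for sub, subval in value.items():
                field_name = _NESTED.get((key, sub))
                if field_name is None:
                    raise PestloadError(f"{path}: unknown config key {key}.{sub}")
                kwargs[field_name] = tuple(subval) if field_name == "crop_codes" else subval
        else:
            raise PestloadError(f"{path}: unknown config key {key}")
    return PipelineConfig(**kwargs)
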