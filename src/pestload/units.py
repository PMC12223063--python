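"""Area units and the state-level pesticide application density.

The application density is the state total mass of active ingredient applied
in a year divided by the state total crop area that year:

    D_P = sum_i F_i / A_T        [kg / km^2]

where ``F_i`` are the reported formulation masses (kg of active ingredient)
and ``A_T`` is the planted crop area in km^2. All arithmetic is carried at
full floating precision; rounding happens only in presentation helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .errors import ConsistencyError, UnitError

#: International acre, exact by definition: 1 acre = 0.0040468564224 km^2.
ACRE_TO_KM2 = 0.0040468564224


class AreaUnit(str, Enum):
    ACRE = "acre"
    KM2 = "km2"


def _coerce_unit(unit: "AreaUnit | str") -> AreaUnit:
    try:
        return AreaUnit(unit)
    except ValueError:
        raise UnitError(f"unrecognized area unit: {unit!r}") from None


def convert_area(value: float, from_unit: "AreaUnit | str", to_unit: "AreaUnit | str") -> float:
    """Convert an area between acres and square kilometres.

    Uses the exact international-acre constant; identity when units agree.
    Raises :class:`UnitError` for unknown units, ``ValueError`` for negative
    areas.
    """
    src, dst = _coerce_unit(from_unit), _coerce_unit(to_unit)
    if value < 0:
        raise ValueError(f"area must be non-negative, got {value}")
    if src is dst:
        return float(value)
    if src is AreaUnit.ACRE:  # -> km2
        return value * ACRE_TO_KM2
    return value / ACRE_TO_KM2


def acres_to_km2(value: float) -> float:
    return convert_area(value, AreaUnit.ACRE, AreaUnit.KM2)


@dataclass(frozen=True)
class PesticideUseRecord:
    """Yearly state-level use of the active ingredient, by formulation.

    ``formulation_kg`` holds the individual reported formulation masses; the
    analysis only ever uses their sum, with no potency weighting (masses are
    already expressed as kg of active ingredient).
    """

    year: int
    formulation_kg: tuple[float, ...]
    region_label: str = ""

    def __post_init__(self):
        if int(self.year) <= 0:
            raise ValueError(f"year must be a positive integer, got {self.year}")
        object.__setattr__(self, "formulation_kg", tuple(float(v) for v in self.formulation_kg))
        for v in self.formulation_kg:
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"formulation mass must be finite and >= 0, got {v}")

    @property
    def total_kg(self) -> float:
        return float(sum(self.formulation_kg))


@dataclass(frozen=True)
class StateCropTotal:
    """State-level planted crop area for one year."""

    year: int
    area: float
    unit: AreaUnit = AreaUnit.KM2

    def __post_init__(self):
        object.__setattr__(self, "unit", _coerce_unit(self.unit))
        if self.area < 0:
            raise ValueError(f"area must be non-negative, got {self.area}")

    @property
    def area_km2(self) -> float:
        return convert_area(self.area, self.unit, AreaUnit.KM2)


@dataclass(frozen=True)
class ApplicationDensity:
    """Pesticide application density D_P for one year, in kg/km^2."""

    year: int
    density_kg_per_km2: float

    def __post_init__(self):
        d = float(self.density_kg_per_km2)
        if not math.isfinite(d) or d < 0:
            raise ValueError(f"density must be finite and >= 0, got {d}")

    def rounded(self, ndigits: int = 2) -> float:
        """Presentation rounding (tables print densities at 2 dp)."""
        return round(self.density_kg_per_km2, ndigits)


def compute_application_density(use: PesticideUseRecord, total: StateCropTotal) -> ApplicationDensity:
    """D_P = sum(F_i) / A_T, with A_T converted to km^2 first."""
    if use.year != total.year:
        raise ConsistencyError(f"use year {use.year} != crop-total year {total.year}")
    area_km2 = total.area_km2
    if area_km2 <= 0:
        raise ValueError(f"total crop area must be > 0 km^2, got {area_km2}")
    return ApplicationDensity(year=use.year, density_kg_per_km2=use.total_kg / area_km2)


def densities_by_year(
    uses: Iterable[PesticideUseRecord], totals: Iterable[StateCropTotal]
) -> dict[int, ApplicationDensity]:
    """Pair use records with crop totals on year and compute each density."""
    totals_by_year = {t.year: t for t in totals}
    out: dict[int, ApplicationDensity] = {}
    for use in uses:
        if use.year not in totals_by_year:
            raise ConsistencyError(f"no crop total for use year {use.year}")
        out[use.year] = compute_application_density(use, totals_by_year[use.year])
    return out
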