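"""Bivariate screening of counties: population density vs pesticide density.

Each county gets a class 1..k (default terciles, k=3) independently on
population density (persons/km^2) and pesticide application density
(kg/km^2). "Counties of concern" are those in the top class on *both* axes —
the darkest cell of a bivariate choropleth. Class breaks default to empirical
quantiles (rank-based, hence invariant to monotone rescaling of an axis);
values tied at a break go to the lower class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError


@dataclass(frozen=True)
class CountyDensityPair:
    county_id: str
    population: float
    county_area_km2: float
    load_kg: float

    def __post_init__(self):
        if self.county_area_km2 <= 0:
            raise ValueError(f"county area must be > 0, got {self.county_area_km2}")
        if self.population < 0 or self.load_kg < 0:
            raise ValueError("population and load must be >= 0")

    @property
    def pop_density(self) -> float:
        return self.population / self.county_area_km2

    @property
    def pesticide_density(self) -> float:
        return self.load_kg / self.county_area_km2


@dataclass(frozen=True)
class BivariateClass:
    county_id: str
    pop_class: int
    pest_class: int
    concern: bool


def county_pesticide_density(load_kg: float, county_area_km2: float) -> float:
    """County-level application density: load (kg) over county area (km^2)."""
    if county_area_km2 <= 0:
        raise ValueError(f"county area must be > 0, got {county_area_km2}")
    if load_kg < 0:
        raise ValueError(f"load must be >= 0, got {load_kg}")
    return load_kg / county_area_km2


def quantile_classify(
    values: Sequence[float],
    n_classes: int = 3,
    method: str = "quantile",
    breaks: "Sequence[float] | None" = None,
) -> list[int]:
    """Classify values into 1..n_classes by quantile or equal-interval breaks.

    ``method="quantile"`` (default) places breaks at the i/n empirical
    quantiles (linear interpolation of order statistics); ``"equal_interval"``
    splits [min, max] evenly; ``"custom"`` uses the provided ``breaks``.
    A value equal to a break belongs to the lower class.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < n_classes:
        raise InsufficientDataError(f"need at least {n_classes} values, got {vals.size}")
    if method == "quantile":
        qs = np.quantile(vals, [i / n_classes for i in range(1, n_classes)], method="linear")
    elif method == "equal_interval":
        qs = np.linspace(vals.min(), vals.max(), n_classes + 1)[1:-1]
    elif method == "custom":
        if breaks is None or len(breaks) != n_classes - 1:
            raise ValueError(f"custom method needs {n_classes - 1} breaks")
        qs = np.asarray(breaks, dtype=float)
    else:
        raise ValueError(f"unknown break method: {method!r}")
    # class = 1 + number of breaks strictly below the value (ties -> lower)
    classes = 1 + (vals[:, None] > qs[None, :]).sum(axis=1)
    return [int(c) for c in classes]


def tercile_classify(values: Sequence[float]) -> list[int]:
    """Three-class quantile classification (the bivariate-map default)."""
    return quantile_classify(values, n_classes=3, method="quantile")


def counties_of_concern(
    pairs: Iterable[CountyDensityPair],
    n_classes: int = 3,
    method: str = "quantile",
) -> list[BivariateClass]:
    """Classify both axes and flag counties in the top class of each.

    Output order matches input order.
    """
    pairs = list(pairs)
    pop_classes = quantile_classify([p.pop_density for p in pairs], n_classes, method)
    pest_classes = quantile_classify([p.pesticide_density for p in pairs], n_classes, method)
    return [
        BivariateClass(
            county_id=p.county_id,
            pop_class=pc,
            pest_class=qc,
            concern=(pc == n_classes and qc == n_classes),
        )
        for p, pc, qc in zip(pairs, pop_classes, pest_classes)
    ]
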