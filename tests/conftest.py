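from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pestload.grids import CropRaster, PopulationGrid
from pestload.synthetic import LandscapeSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def small_spec():
    """A fast 6 km x 6 km landscape for unit tests."""
    return LandscapeSpec(
        extent_m=(6000.0, 6000.0),
        crop_cell_m=30.0,
        pop_cell_m=1000.0,
        crop_fraction=0.30,
        n_field_seeds=12,
        field_growth_steps=300,
        n_pop_hotspots=1,
        total_population=5000,
        hotspot_decay_m=1500.0,
        seed=42,
    )


def random_crop_raster(rng, n_rows, n_cols, cell_size_m=30.0, crop_prob=0.4,
                       origin=(0.0, None), crop_code=5):
    """Bernoulli crop raster with a top-left origin derived from its size."""
    oy = origin[1] if origin[1] is not None else n_rows * cell_size_m
    values = np.where(rng.random((n_rows, n_cols)) < crop_prob, crop_code, 0).astype(np.uint8)
    return CropRaster(origin=(origin[0], oy), cell_size_m=cell_size_m,
                      values=values, crop_codes=frozenset({crop_code}))


@pytest.fixture
def uniform_population():
    """3x3 populated grid, 100 persons per cell."""
    return PopulationGrid(origin=(0.0, 3000.0), cell_size_m=1000.0,
                          counts=np.full((3, 3), 100.0))
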