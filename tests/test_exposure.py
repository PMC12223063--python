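"""The 1 km crop-area buffer model and population exposure summaries."""

import math

import numpy as np
import pytest

from conftest import random_crop_raster
from helpers import disc_area_loop_km2
from pestload import (
    ApplicationDensity,
    BufferExposureRecord,
    BufferSpec,
    CropRaster,
    ExposureSummary,
    ExposureThresholds,
    PopulationGrid,
    buffer_crop_area,
    buffer_load,
    cell_center,
    classify_exposure,
    compute_buffer_records,
    exposure_change,
    exposure_summary,
)
from pestload.errors import ConsistencyError, CoverageError


class TestCellCenter:
    def test_known_geometry(self):
        grid = PopulationGrid(origin=(0.0, 1000.0), cell_size_m=1000.0,
                              counts=np.ones((1, 2)))
        assert cell_center(grid, 0, 0) == (500.0, 500.0)
        assert cell_center(grid, 0, 1) == (1500.0, 500.0)

    def test_matches_affine_oracle(self, rng):
        for _ in range(20):
            ox, oy = rng.uniform(-5e4, 5e4, size=2)
            cell = rng.uniform(5, 2000)
            nr, nc = rng.integers(1, 40, size=2)
            grid = PopulationGrid(origin=(ox, oy), cell_size_m=cell,
                                  counts=np.ones((nr, nc)))
            r = int(rng.integers(0, nr))
            c = int(rng.integers(0, nc))
            x, y = cell_center(grid, r, c)
            assert x == pytest.approx(ox + (c + 0.5) * cell, rel=1e-12)
            assert y == pytest.approx(oy - (r + 0.5) * cell, rel=1e-12)

    def test_out_of_range(self):
        grid = PopulationGrid(origin=(0, 0), cell_size_m=1.0, counts=np.ones((2, 2)))
        with pytest.raises(IndexError):
            cell_center(grid, 2, 0)


def test_buffer_spec_totals_one_km():
    spec = BufferSpec()
    assert spec.core_radius_m == 250 and spec.donut_width_m == 750
    assert spec.total_radius_m == 1000


class TestBufferCropArea:
    def test_all_crop_disc_is_pi(self):
        """All-crop 10 m raster: 1 km disc area within 0.5% of pi km^2."""
        values = np.full((300, 300), 5, dtype=np.uint8)
        raster = CropRaster(origin=(0.0, 3000.0), cell_size_m=10.0, values=values)
        area = buffer_crop_area(raster, (1500.0, 1500.0), 1000.0)
        assert area == pytest.approx(math.pi, rel=0.005)

    def test_all_noncrop(self):
        values = np.zeros((100, 100), dtype=np.uint8)
        raster = CropRaster(origin=(0.0, 3000.0), cell_size_m=30.0, values=values)
        assert buffer_crop_area(raster, (1500.0, 1500.0), 1000.0) == 0.0

    def test_center_far_outside_raster(self):
        values = np.full((10, 10), 5, dtype=np.uint8)
        raster = CropRaster(origin=(0.0, 300.0), cell_size_m=30.0, values=values)
        assert buffer_crop_area(raster, (1e6, 1e6), 1000.0) == 0.0

    def test_matches_exhaustive_loop_oracle(self, rng):
        """Exact equality with the per-cell Python distance oracle."""
        for _ in range(6):
            raster = random_crop_raster(rng, 70, 70, cell_size_m=30.0,
                                        crop_prob=rng.uniform(0.2, 0.8))
            for _ in range(8):
                center = (rng.uniform(-200, 2300), rng.uniform(-200, 2300))
                assert buffer_crop_area(raster, center, 1000.0) == disc_area_loop_km2(
                    raster, center, 1000.0
                )

    def test_area_bounded_by_disc(self, rng):
        bound = math.pi * 1.0**2
        raster = random_crop_raster(rng, 100, 100, cell_size_m=30.0, crop_prob=1.0)
        for _ in range(10):
            center = (rng.uniform(0, 3000), rng.uniform(0, 3000))
            # one extra boundary row of cell centers can fall inside the disc
            assert buffer_crop_area(raster, center, 1000.0) <= bound * 1.01


class TestBufferLoad:
    def test_proximity_area_at_start_density(self):
        # 0.04 km^2 of crop at 11.25 kg/km^2 -> 0.45 kg in the buffer
        assert buffer_load(0.04, ApplicationDensity(2017, 11.25)) == pytest.approx(0.45)

    def test_zero_area(self):
        assert buffer_load(0.0, ApplicationDensity(2023, 50.41)) == 0.0

    def test_algebraic_inversion(self):
        """Crop area needed to reach the 4.4 kg threshold at the end density."""
        d = ApplicationDensity(2023, 50.41)
        area_needed = 4.4 / d.density_kg_per_km2
        assert area_needed == pytest.approx(0.0873, abs=5e-5)
        assert buffer_load(area_needed, d) == pytest.approx(4.4, rel=1e-12)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            buffer_load(-0.1, ApplicationDensity(2017, 1.0))


def _record(cell, pop, area, load, year=2017):
    return BufferExposureRecord(cell_id=cell, center=(0.0, 0.0), population=pop,
                                crop_area_km2=area, load_kg=load, year=year)


class TestClassifyExposure:
    def test_boundary_inclusivity(self):
        """Thresholds are 'at least': equality counts as exposed."""
        rec = _record((0, 0), 10, 0.04, 4.4)
        [flags] = classify_exposure([rec])
        assert flags.proximity is True and flags.dust is True and flags.reference is False

    def test_zero_crop_all_false(self):
        [flags] = classify_exposure([_record((0, 0), 10, 0.0, 0.0)])
        assert not (flags.proximity or flags.dust or flags.reference)

    def test_batch_matches_comparison_loop(self, rng):
        thr = ExposureThresholds()
        records = [
            _record((0, i), 1, a, w)
            for i, (a, w) in enumerate(zip(rng.uniform(0, 0.2, 50), rng.uniform(0, 40, 50)))
        ]
        flags = classify_exposure(records, thr)
        for r, f in zip(records, flags):
            assert f.proximity == (r.crop_area_km2 >= thr.proximity_min_crop_km2)
            assert f.dust == (r.load_kg >= thr.dust_threshold_kg)
            assert f.reference == (r.load_kg >= thr.reference_kg)

    def test_mixed_years_rejected(self):
        with pytest.raises(ConsistencyError):
            classify_exposure([_record((0, 0), 1, 0, 0, 2017), _record((0, 1), 1, 0, 0, 2023)])


class TestExposureSummary:
    def test_saturation(self, uniform_population):
        records = [_record(c, 100, 1.0, 50.0) for c in uniform_population.populated_cells()]
        flags = classify_exposure(records)
        s = exposure_summary(uniform_population, records, flags, "dust")
        assert s.exposed_fraction_pct == 100.0
        assert s.exposed_population == uniform_population.total_population

    def test_nothing_flagged(self, uniform_population):
        records = [_record(c, 100, 0.0, 0.0) for c in uniform_population.populated_cells()]
        flags = classify_exposure(records)
        s = exposure_summary(uniform_population, records, flags, "dust")
        assert s.exposed_fraction_pct == 0.0 and s.exposed_population == 0.0

    def test_constructed_ground_truth_fraction(self):
        """Hand-built landscape: exactly 250 of 1000 people over threshold."""
        counts = np.array([[250.0, 300.0], [450.0, 0.0]])
        pop = PopulationGrid(origin=(0.0, 2000.0), cell_size_m=1000.0, counts=counts)
        records = [
            _record((0, 0), 250, 0.5, 25.0),  # dust-exposed
            _record((0, 1), 300, 0.01, 0.5),
            _record((1, 0), 450, 0.05, 2.0),
        ]
        flags = classify_exposure(records)
        s = exposure_summary(pop, records, flags, "dust")
        assert s.exposed_fraction_pct == 25.0
        assert s.n_cells_exposed == 1

    def test_missing_populated_cell(self, uniform_population):
        records = [_record((0, 0), 100, 0.0, 0.0)]
        flags = classify_exposure(records)
        with pytest.raises(CoverageError) as err:
            exposure_summary(uniform_population, records, flags, "dust")
        assert (1, 1) in err.value.missing_cells


class TestExposureChange:
    def _summary(self, pop, frac, rule="reference"):
        return ExposureSummary(year=2017, rule=rule, threshold=30.0,
                               exposed_population=pop, exposed_fraction_pct=frac,
                               n_cells_exposed=1, total_population=100.0)

    def test_published_magnitude(self):
        """14 -> ~47,000 people is a >330,000% increase."""
        ch = exposure_change(self._summary(14, 0.01), self._summary(47_000, 20.2))
        assert ch.population_pct_change == pytest.approx(335_614.29, abs=0.01)
        assert ch.population_pct_change > 330_000

    def test_identical_summaries(self):
        ch = exposure_change(self._summary(10, 1.0), self._summary(10, 1.0))
        assert ch.population_change == 0.0 and ch.population_pct_change == 0.0

    def test_zero_baseline_undefined(self):
        ch = exposure_change(self._summary(0, 0.0), self._summary(10, 1.0))
        assert not ch.pct_change_defined and math.isnan(ch.population_pct_change)

    def test_rule_mismatch(self):
        with pytest.raises(ConsistencyError):
            exposure_change(self._summary(1, 1.0, "dust"), self._summary(1, 1.0, "reference"))


class TestEndToEndProperties:
    def _fraction(self, pop, crop, density_value, rule, thresholds=ExposureThresholds()):
        density = ApplicationDensity(2020, density_value)
        records = compute_buffer_records(pop, crop, density)
        flags = classify_exposure(records, thresholds)
        return exposure_summary(pop, records, flags, rule, thresholds).exposed_fraction_pct

    def test_monotone_in_density(self, rng, uniform_population):
        crop = random_crop_raster(rng, 100, 100, crop_prob=0.25)
        fracs = [self._fraction(uniform_population, crop, d, "dust")
                 for d in (1.0, 5.0, 11.25, 25.0, 50.41)]
        assert fracs == sorted(fracs)

    def test_monotone_in_threshold(self, rng, uniform_population):
        crop = random_crop_raster(rng, 100, 100, crop_prob=0.25)
        density = ApplicationDensity(2020, 50.41)
        records = compute_buffer_records(uniform_population, crop, density)
        fracs = []
        for t in (1.0, 2.0, 4.4, 10.0, 30.0):
            thr = ExposureThresholds(dust_threshold_kg=t)
            flags = classify_exposure(records, thr)
            fracs.append(
                exposure_summary(uniform_population, records, flags, "dust", thr)
                .exposed_fraction_pct
            )
        assert fracs == sorted(fracs, reverse=True)

    def test_loads_bounded_by_disc_area_times_density(self, rng, uniform_population):
        crop = random_crop_raster(rng, 100, 100, crop_prob=1.0)
        d = ApplicationDensity(2020, 50.41)
        records = compute_buffer_records(uniform_population, crop, d)
        bound = math.pi * 1.0**2 * 1.01  # + boundary-cell discretization
        for r in records:
            assert r.crop_area_km2 <= bound
            assert r.load_kg <= bound * d.density_kg_per_km2

    def test_coarse_crop_raster_warns(self, uniform_population, caplog):
        coarse = CropRaster(origin=(0.0, 3000.0), cell_size_m=500.0,
                            values=np.full((6, 6), 5, dtype=np.uint8))
        with caplog.at_level("WARNING"):
            compute_buffer_records(uniform_population, coarse, ApplicationDensity(2020, 1.0))
        assert "coarser" in caplog.text
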