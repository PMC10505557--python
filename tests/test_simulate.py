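"""Synthetic-data generators: determinism, ground-truth encoding, noise."""

import numpy as np
import pytest

import lignoporo as lp
from lignoporo.errors import DomainError

from conftest import five_bin_distribution, matching_program


class TestDeterminism:
    def test_isotherm_generator(self, reference_park, nine_point_grid):
        a = lp.gen_park_isotherm(reference_park, nine_point_grid, 0.02, seed=7)
        b = lp.gen_park_isotherm(reference_park, nine_point_grid, 0.02, seed=7)
        np.testing.assert_array_equal(a.mass_gain_pct, b.mass_gain_pct)

    def test_kinetics_generator(self):
        kwargs = dict(schedule=[(0.3, 7200.0)], noise_sd=0.01, seed=5)
        a = lp.gen_dvs_kinetics(**kwargs)
        b = lp.gen_dvs_kinetics(**kwargs)
        np.testing.assert_array_equal(a.mass_mg, b.mass_mg)

    def test_image_generator(self):
        a = lp.gen_image_stack(seed=9)
        b = lp.gen_image_stack(seed=9)
        np.testing.assert_array_equal(a.target, b.target)
        assert not np.array_equal(a.target, lp.gen_image_stack(seed=10).target)

    def test_groups_generator(self):
        spec = [("a", "normal", 0.0, 1.0, 5)]
        a = lp.gen_grouped_measurements(spec, seed=3).frame
        b = lp.gen_grouped_measurements(spec, seed=3).frame
        assert a.equals(b)


class TestParkIsothermGenerator:
    def test_pure_henry_limit(self):
        p = lp.ParkParameters(1.0, 0.0, 5.0, 0.0, 2.0)
        iso = lp.gen_park_isotherm(p, [0.2, 0.4], 0.0)
        np.testing.assert_allclose(iso.mass_gain_pct, [1.0, 2.0], rtol=1e-14)

    def test_zero_noise_reproduces_model(self, reference_park, nine_point_grid):
        iso = lp.gen_park_isotherm(reference_park, nine_point_grid, 0.0)
        np.testing.assert_allclose(
            iso.mass_gain_pct, lp.park_model(reference_park, nine_point_grid), rtol=1e-14
        )

    @pytest.mark.parametrize("grid", [[0.5, 0.4], [-0.1, 0.5], [0.5, 1.0]])
    def test_invalid_grids_rejected(self, reference_park, grid):
        with pytest.raises(DomainError):
            lp.gen_park_isotherm(reference_park, grid, 0.0)

    def test_negative_noise_rejected(self, reference_park):
        with pytest.raises(DomainError):
            lp.gen_park_isotherm(reference_park, [0.5], -0.1)


class TestKineticsGenerator:
    def test_dry_hold_is_flat_at_dry_mass(self):
        trace = lp.gen_dvs_kinetics(schedule=[(0.0, 3600.0)], dry_mass_mg=20.0)
        np.testing.assert_allclose(trace.mass_mg, 20.0, rtol=1e-12)

    def test_terminal_mass_near_park_equilibrium(self):
        trace = lp.gen_dvs_kinetics(schedule=[(0.5, 12 * 1200.0)])
        m_inf = 20.0 * (1 + lp.park_model(lp.DEFAULT_PARK_PARAMS, 0.5) / 100.0)
        assert trace.mass_mg[-1] == pytest.approx(m_inf, rel=1e-3)

    def test_empty_schedule_rejected(self):
        with pytest.raises(DomainError):
            lp.gen_dvs_kinetics(schedule=[])


class TestDSCGenerator:
    def test_energy_conservation(self):
        dist = five_bin_distribution(seed=2)
        program = matching_program(dist)
        tg = lp.gen_dsc_thermogram(dist, program)
        total_mj = np.trapezoid(tg.heat_flow_mw, tg.time_s)
        expected = dist.total_freezing_water_mg * 334.0
        assert total_mj == pytest.approx(expected, rel=0.005)

    def test_zero_freezing_water_gives_baseline_only(self):
        dist = five_bin_distribution(seed=2, total_mg=3.0)
        program = matching_program(dist)
        silent = lp.PoreSizeDistribution(dist.bins, dist.free_water_fraction, 0.0)
        tg = lp.gen_dsc_thermogram(silent, program, baseline_mw=0.25)
        np.testing.assert_allclose(tg.heat_flow_mw, 0.25, atol=1e-12)

    def test_two_equal_bins_equal_peak_areas(self):
        edges = np.array([8e-9, 16e-9, 32e-9])
        dist = lp.PoreSizeDistribution(
            [(edges[0], edges[1], 50.0), (edges[1], edges[2], 50.0)], 0.0, 2.0
        )
        program = matching_program(dist)
        tg = lp.gen_dsc_thermogram(dist, program)
        windows = lp.segment_steps(tg, program)
        areas = [lp.integrate_endotherm(w, tg) for w in windows]
        peaks = [a for a in areas if a > 1e-6]
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(peaks[1], rel=0.001)

    def test_sign_convention_declared(self):
        dist = five_bin_distribution(seed=2)
        tg = lp.gen_dsc_thermogram(dist, matching_program(dist))
        assert tg.metadata["sign_convention"] == "endotherm_up"

    def test_mismatched_program_rejected(self):
        dist = five_bin_distribution(seed=2)
        bad = lp.StepProgram([(250.0, 600.0), (275.15, 600.0)])
        with pytest.raises(DomainError):
            lp.gen_dsc_thermogram(dist, bad)


class TestImageGenerator:
    def test_counterstain_nonzero_exactly_on_walls(self):
        stack = lp.gen_image_stack(noise_sd=0.0, seed=0)
        proj = stack.counterstain.max(axis=0)
        np.testing.assert_array_equal(proj > 0, stack.truth_mask)

    def test_programmed_levels_on_focal_plane(self):
        stack = lp.gen_image_stack(
            noise_sd=0.0, target_levels=(100.0, 0.0), seed=0
        )
        assert stack.target[0][stack.truth_mask].max() == pytest.approx(100.0)

    def test_wall_intensity_must_exceed_background(self):
        with pytest.raises(DomainError):
            lp.gen_image_stack(target_levels=(10.0, 100.0))

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(DomainError):
            lp.gen_image_stack(
                shape=(1, 16, 16),
                wall_geometry=lp.HoneycombGeometry(cell_radius_px=100.0),
            )


class TestGroupsGenerator:
    def test_moments_of_normal_draws(self):
        data = lp.gen_grouped_measurements([("a", "normal", 5.0, 2.0, 4000)], seed=0)
        v = data.group_values()["a"]
        assert v.mean() == pytest.approx(5.0, abs=0.15)
        assert v.std() == pytest.approx(2.0, abs=0.15)

    def test_unsupported_distribution_rejected(self):
        with pytest.raises(DomainError):
            lp.gen_grouped_measurements([("a", "cauchy", 0.0, 1.0, 5)], seed=0)

    def test_minimum_group_size_enforced(self):
        with pytest.raises(DomainError):
            lp.gen_grouped_measurements([("a", "normal", 0.0, 1.0, 2)], seed=0)

    def test_zero_sd_yields_constants(self):
        data = lp.gen_grouped_measurements([("a", "normal", 3.0, 0.0, 3)], seed=0)
        assert np.ptp(data.group_values()["a"]) == 0.0
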