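"""Gibbs-Thomson inversion, thermogram segmentation and pore distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lignoporo as lp
from lignoporo.errors import DegenerateDataError, DomainError, SegmentationError
from lignoporo.thermoporometry import StepWindow

from conftest import five_bin_distribution, matching_program

T0 = 273.15


class TestGibbsThomson:
    def test_one_kelvin_depression_against_arithmetic(self):
        # brute-force: 4 * 273.15 * 0.0121 / (1 * 1000 * 334000)
        expected = 4 * 273.15 * 0.0121 / (1000.0 * 334000.0)
        assert lp.gibbs_thomson_diameter(T0 - 1.0) == pytest.approx(expected, rel=1e-12)
        assert lp.gibbs_thomson_diameter(T0 - 1.0) == pytest.approx(39.6e-9, rel=1e-3)

    def test_inverse_scaling_with_depression(self):
        d1 = lp.gibbs_thomson_diameter(T0 - 1.0)
        d10 = lp.gibbs_thomson_diameter(T0 - 10.0)
        assert d10 == pytest.approx(d1 / 10.0, rel=1e-12)

    def test_at_or_above_t0_rejected(self):
        for tm in (T0, T0 + 1.0):
            with pytest.raises(DomainError):
                lp.gibbs_thomson_diameter(tm)

    @given(st.floats(0.01, 60.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_depression_and_product_constant(self, dT):
        d = lp.gibbs_thomson_diameter(T0 - dT)
        d2 = lp.gibbs_thomson_diameter(T0 - dT * 1.5)
        assert d2 < d
        ref = lp.gibbs_thomson_diameter(T0 - 1.0)
        assert d * dT == pytest.approx(ref, rel=1e-10)

    def test_round_trip_with_inverse(self):
        rng = np.random.default_rng(0)
        diameters = rng.uniform(1e-9, 500e-9, 100)
        tm = lp.melting_temperature_for_diameter(diameters)
        back = lp.gibbs_thomson_diameter(tm)
        np.testing.assert_allclose(back, diameters, rtol=1e-10)

    def test_mesopore_window_unit_audit(self):
        # with the default constants, depressions of 1.24-9.9 K bracket the
        # 4-32 nm mesopore analysis window
        d_hi = lp.gibbs_thomson_diameter(T0 - 1.24)
        d_lo = lp.gibbs_thomson_diameter(T0 - 9.9)
        assert 3.9e-9 < d_lo < 4.1e-9
        assert 31e-9 < d_hi < 33e-9

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(DomainError):
            lp.melting_temperature_for_diameter(0.0)


class TestSegmentation:
    def test_windows_match_generator_holds(self):
        dist = five_bin_distribution()
        program = matching_program(dist)
        tg = lp.gen_dsc_thermogram(dist, program)
        # a tight temperature band keeps ramp samples out of the windows
        windows = lp.segment_steps(tg, program, temperature_tolerance=0.01)
        assert len(windows) == len(program.holds)
        for w, (hold_T, duration) in zip(windows, program.holds):
            assert w.hold_temperature_K == hold_T
            times = tg.time_s[w.start : w.stop]
            assert times[-1] - times[0] == pytest.approx(duration, abs=3.0)

    def test_flat_trace_single_full_window(self):
        t = np.arange(0, 600.0, 1.0)
        tg = lp.DSCThermogram(t, np.full(t.size, 263.15), np.zeros(t.size), 8.0)
        program = lp.StepProgram([(263.15, 600.0)])
        (w,) = lp.segment_steps(tg, program)
        assert (w.start, w.stop) == (0, t.size)

    def test_missing_hold_named_in_error(self):
        t = np.arange(0, 600.0, 1.0)
        tg = lp.DSCThermogram(t, np.full(t.size, 263.15), np.zeros(t.size), 8.0)
        program = lp.StepProgram([(263.15, 300.0), (270.15, 300.0)])
        with pytest.raises(SegmentationError, match="-3.00"):
            lp.segment_steps(tg, program)


class TestIntegration:
    def _flat_thermogram(self, hf):
        t = np.arange(0, hf.size, 1.0)
        return lp.DSCThermogram(t, np.full(t.size, 263.15), hf, sample_mass_mg=8.0)

    def test_baseline_only_window_is_zero(self):
        tg = self._flat_thermogram(np.full(600, 0.37))
        w = StepWindow(0, 600, 263.15)
        assert lp.integrate_endotherm(w, tg) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_peak_area_recovered(self):
        t = np.arange(0, 600.0, 1.0)
        area = 500.0  # mJ
        sigma = 25.0
        hf = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - 300) / sigma) ** 2)
        tg = self._flat_thermogram(hf)
        got = lp.integrate_endotherm(StepWindow(0, 600, 263.15), tg)
        assert got == pytest.approx(area / 8.0, rel=0.005)

    def test_sloped_baseline_cancels_in_linear_mode(self):
        t = np.arange(0, 600.0, 1.0)
        tg = self._flat_thermogram(0.01 * t + 0.2)
        got = lp.integrate_endotherm(StepWindow(0, 600, 263.15), tg, baseline="linear")
        assert got == pytest.approx(0.0, abs=0.005 * 0.01 * 600 * 600 / 8)

    def test_single_bin_peak_area_encodes_water_mass(self):
        # one hold carrying 2 mg of pore water -> integral = 2 mg * 334 J/g
        edges = np.array([10e-9, 20e-9])
        dist = lp.PoreSizeDistribution([(edges[0], edges[1], 100.0)], 0.0, 2.0)
        program = matching_program(dist)
        tg = lp.gen_dsc_thermogram(dist, program)
        windows = lp.segment_steps(tg, program)
        enths = [lp.integrate_endotherm(w, tg) for w in windows]
        total_mj = sum(enths) * tg.sample_mass_mg
        assert total_mj == pytest.approx(2.0 * 334.0, rel=0.005)


class TestPoreDistribution:
    def test_single_hold_all_water(self):
        dist = lp.pore_distribution(
            [(T0 - 5.0, 167.0)], sample_mass_mg=8.0, start_temperature_K=T0 - 30.0
        )
        assert len(dist.bins) == 1
        assert dist.bins[0][2] == pytest.approx(100.0)
        assert dist.free_water_fraction == 0.0

    def test_two_equal_enthalpies_split_evenly(self):
        dist = lp.pore_distribution(
            [(T0 - 5.0, 167.0), (T0 - 2.0, 167.0)],
            sample_mass_mg=8.0,
            start_temperature_K=T0 - 30.0,
        )
        assert dist.bins[0][2] == pytest.approx(50.0)
        assert dist.bins[1][2] == pytest.approx(50.0)
        # 167 J/g * 8 mg / 334 J/g = 4 mg each
        assert dist.total_freezing_water_mg == pytest.approx(8.0)

    def test_all_zero_enthalpies_rejected(self):
        with pytest.raises(DegenerateDataError):
            lp.pore_distribution([(T0 - 5.0, 0.0)], sample_mass_mg=8.0)

    def test_round_trip_recovers_distribution(self):
        truth = five_bin_distribution(seed=21)
        program = matching_program(truth)
        tg = lp.gen_dsc_thermogram(truth, program)
        rec = lp.Thermoporometry(tg, program).fit()
        true_fracs = np.array([b[2] for b in truth.bins])
        rec_fracs = np.array([b[2] for b in rec.bins])
        np.testing.assert_allclose(rec_fracs, true_fracs, atol=2.0)
        assert rec.free_water_fraction == pytest.approx(truth.free_water_fraction, abs=2.0)
        assert rec.total_freezing_water_mg == pytest.approx(
            truth.total_freezing_water_mg, rel=0.005
        )

    def test_fraction_sum_invariant_enforced(self):
        with pytest.raises(DomainError):
            lp.PoreSizeDistribution([(4e-9, 8e-9, 50.0)], 30.0, 1.0)


class TestWaterContent:
    @pytest.mark.parametrize(
        "sat,dry,expected", [(10.0, 4.0, 60.0), (8.0, 8.0, 0.0)]
    )
    def test_examples(self, sat, dry, expected):
        assert lp.total_water_content(sat, dry) == pytest.approx(expected)

    @pytest.mark.parametrize("sat,dry", [(8.0, 0.0), (4.0, 5.0), (0.0, 0.0)])
    def test_domain_errors(self, sat, dry):
        with pytest.raises(DomainError):
            lp.total_water_content(sat, dry)
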