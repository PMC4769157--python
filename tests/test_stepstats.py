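"""Histogramming, the missed-step mixture fit, calibration, lifetimes,
and FRET-distance conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nucstep as ns
from nucstep.mixture import step_mixture_model


class TestHistogram:
    def test_binning_examples(self):
        h = ns.build_step_histogram([0.1, 0.1, 0.3], bin_width=0.02)
        assert h.counts[5] == 2   # [0.10, 0.12)
        assert h.counts[15] == 1  # [0.30, 0.32)
        assert h.n_steps == 3

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        steps = rng.uniform(0.01, 0.4, 500)
        h = ns.build_step_histogram(steps)
        assert h.n_steps == 500

    def test_modes_near_c_and_2c(self):
        x = ns.simulate_step_observations(0.1, 0.3, 0.015, 1000, seed=5)
        h = ns.build_step_histogram(x, 0.02)
        # mode in the [0.08, 0.12) region; secondary bump near 0.2
        assert abs(h.x[np.argmax(h.counts)] - 0.1) <= 0.02
        near_2c = h.counts[(h.x > 0.16) & (h.x < 0.24)].max()
        trough = h.counts[(h.x > 0.13) & (h.x < 0.17)].min()
        assert near_2c > trough

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ns.build_step_histogram([])


class TestEqOneFit:
    def test_noiseless_self_consistency(self):
        """Exact model curve refit recovers (A, f, c, s) to 1e-6."""
        x = np.arange(0.01, 0.8, 0.02)
        y = step_mixture_model(x, A=100.0, f=0.30, c=0.10, s=0.02, n_max=6)
        hist = ns.StepSizeHistogram(
            bin_edges=np.arange(0.0, 0.81, 0.02), counts=y)
        fit, = ns.fit_eq1(hist)
        assert fit.A == pytest.approx(100.0, abs=1e-6)
        assert fit.f == pytest.approx(0.30, abs=1e-6)
        assert fit.c == pytest.approx(0.10, abs=1e-6)
        assert fit.s == pytest.approx(0.02, abs=1e-6)

    def test_single_gaussian_limit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.10, 0.02, 2000)
        hist = ns.build_step_histogram(x, 0.01)
        fit, = ns.fit_eq1(hist)
        assert fit.c == pytest.approx(0.10, abs=0.005)
        assert fit.f == pytest.approx(0.0, abs=0.05)

    def test_parameter_recovery_from_samples(self):
        x = ns.simulate_step_observations(0.10, 0.35, 0.025, 1000, seed=17)
        hist = ns.build_step_histogram(x, 0.02)
        fit, = ns.fit_eq1(hist)
        assert fit.c == pytest.approx(0.10, abs=0.005)
        assert fit.f == pytest.approx(0.35, abs=0.05)

    def test_shared_s_across_histograms(self):
        h = []
        for seed, (c, f) in zip((1, 2), ((0.09, 0.2), (0.12, 0.4))):
            x = ns.simulate_step_observations(c, f, 0.02, 1500, seed=seed)
            h.append(ns.build_step_histogram(x, 0.02, movement_type="exit"))
        fits = ns.fit_eq1(h, shared_s=True)
        assert fits[0].s == fits[1].s  # one global width
        assert fits[0].c == pytest.approx(0.09, abs=0.01)
        assert fits[1].c == pytest.approx(0.12, abs=0.01)

    def test_mixed_movement_types_rejected(self):
        x = ns.simulate_step_observations(0.1, 0.3, 0.02, 500, seed=0)
        h1 = ns.build_step_histogram(x, 0.02, movement_type="exit")
        h2 = ns.build_step_histogram(x, 0.02, movement_type="entry")
        with pytest.raises(ValueError, match="movement types"):
            ns.fit_eq1([h1, h2])

    def test_peak_amplitude_ratio_equals_f(self):
        """For well-separated peaks the model amplitude at 2c over that
        at c equals f."""
        fit = ns.EqOneFit(A=50.0, f=0.4, c=0.15, s=0.01, A_se=0, f_se=0,
                          c_se=0, s_se=0, n_max=6, shared_s=True,
                          redchi=0.0, f_at_bound=False)
        ratio = fit.model(2 * 0.15) / fit.model(0.15)
        assert ratio == pytest.approx(0.4, abs=1e-6)


class TestGaussianAndCalibration:
    def test_gaussian_mean_recovery(self):
        rng = np.random.default_rng(21)
        g = ns.fit_gaussian_fret(rng.normal(0.6, 0.05, 5000))
        assert g.mean == pytest.approx(0.6, abs=0.002)
        assert g.sd == pytest.approx(0.05, rel=0.1)
        assert g.good_fit

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            ns.fit_gaussian_fret(np.full(100, 0.5))
        with pytest.raises(ValueError):
            ns.fit_gaussian_fret(np.random.default_rng(0).normal(0.5, 0.1, 10))

    def test_bimodal_flagged(self):
        rng = np.random.default_rng(5)
        x = np.r_[rng.normal(0.2, 0.02, 2000), rng.normal(0.7, 0.02, 2000)]
        assert not ns.fit_gaussian_fret(x).good_fit

    def test_exact_line(self):
        curve = ns.fit_calibration([(0, 0.3), (6, 0.6), (12, 0.9)])
        assert curve.slope == pytest.approx(0.05)
        assert curve.slope_se == pytest.approx(0.0, abs=1e-8)
        assert curve.fret_range == (pytest.approx(0.3), pytest.approx(0.9))

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            ns.fit_calibration([(0, 0.3), (6, 0.6)])

    def test_noisy_slope_recovery(self):
        df = ns.simulate_calibration_dataset(0.053, 0.1, [0, 3, 6, 9, 12, 15],
                                             0.03, 200, seed=2)
        points = [(L, ns.fit_gaussian_fret(g["fret"].to_numpy()).mean)
                  for L, g in df.groupby("linker_bp")]
        curve = ns.fit_calibration(points)
        assert abs(curve.slope - 0.053) < 2 * max(curve.slope_se, 1e-4)


class TestBpConversion:
    @pytest.mark.parametrize("c,c_se,slope,slope_se,bp,bp_se", [
        (0.104, 0.002, 0.053, 0.004, 2.0, 0.2),
        (0.113, 0.003, 0.059, 0.005, 1.9, 0.2),
        (0.092, 0.004, 0.057, 0.002, 1.6, 0.1),
        (0.088, 0.002, 0.055, 0.002, 1.6, 0.1),
    ])
    def test_published_style_conversions(self, c, c_se, slope, slope_se, bp, bp_se):
        cal = ns.calibration_from_slope(slope, slope_se)
        got, got_se = ns.convert_step_to_bp(c, c_se, cal)
        assert round(got, 1) == bp
        assert round(got_se, 1) == bp_se

    def test_linearity_in_slope(self):
        one = ns.convert_step_to_bp(0.1, 0.0, ns.calibration_from_slope(0.05))[0]
        two = ns.convert_step_to_bp(0.1, 0.0, ns.calibration_from_slope(0.10))[0]
        assert one == pytest.approx(2 * two)

    def test_zero_step(self):
        assert ns.convert_step_to_bp(0.0, 0.0, ns.calibration_from_slope(0.05)) \
            == (0.0, 0.0)


class TestPauseLifetimes:
    def test_truncated_tau_recovery(self):
        raw = ns.simulate_pause_lifetimes(20.0, 10_000, seed=4)
        truncated = raw + 5.0  # memorylessness: shifted = conditioned on >= 5
        fit = ns.fit_pause_lifetimes(truncated, frame_rate=1.0, threshold=5)
        assert fit.tau_frames == pytest.approx(20.0, abs=0.5)
        assert fit.missed_fraction == pytest.approx(1 - math.exp(-0.25), abs=1e-2)

    def test_missed_fraction_analytics(self):
        assert ns.missed_fraction(20.0, 5.0) == pytest.approx(0.221, abs=1e-3)
        assert ns.missed_fraction(20.0, 0.0) == 0.0
        assert ns.missed_fraction(5.0 / math.log(2), 5.0) == pytest.approx(0.5, abs=1e-12)

    def test_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            ns.fit_pause_lifetimes(np.full(30, 3.0), threshold=5)

    @given(tau=st.floats(min_value=1.0, max_value=200.0))
    @settings(deadline=None, max_examples=30)
    def test_missed_fraction_decreasing_in_tau(self, tau):
        assert ns.missed_fraction(tau + 1.0, 5.0) < ns.missed_fraction(tau, 5.0)


class TestFretDistance:
    def test_half_efficiency_at_r0(self):
        assert ns.fret_to_distance(0.5, 6.0) == pytest.approx(6.0)

    def test_small_step_distance_change(self):
        dr = ns.distance_change(0.6, 0.5, 6.0)
        assert dr == pytest.approx(0.39, abs=0.01)

    def test_typical_step_changes_within_half_nm(self):
        """ΔFRET ~ 0.1 anywhere in the mid-FRET range corresponds to
        ~0.3-0.6 nm of dye motion."""
        for f1 in np.arange(0.45, 0.66, 0.05):
            dr = ns.distance_change(f1, f1 - 0.1, 6.0)
            assert 0.3 <= dr <= 0.6

    def test_bounds_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                ns.fret_to_distance(bad)

    @given(f=st.floats(min_value=0.01, max_value=0.99))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_and_monotonicity(self, f):
        from nucstep.calibrate import distance_to_fret
        r = ns.fret_to_distance(f)
        assert ns.fret_to_distance(
            distance_to_fret(r)) == pytest.approx(r, abs=1e-10)
        assert ns.fret_to_distance(min(f + 0.005, 0.995)) < r or f > 0.99
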