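"""Trace I/O, bleach detection, background subtraction, FRET, filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nucstep as ns
from nucstep.traces import TRACE_COLUMNS


def _trace(donor, acceptor, rate=1.0, construct=None, name=""):
    return ns.IntensityTrace(donor=np.asarray(donor, float),
                             acceptor=np.asarray(acceptor, float),
                             frame_rate=rate, construct=construct, name=name)


class TestIO:
    def test_round_trip(self, tmp_path, end6):
        t = _trace([1.5, 2.0, 3.25], [0.5, 0.25, 0.125], rate=8.0,
                   construct=end6, name="m0")
        manifest = ns.write_traces([t], tmp_path)
        back, = ns.read_traces(manifest)
        np.testing.assert_allclose(back.donor, t.donor)
        np.testing.assert_allclose(back.acceptor, t.acceptor)
        assert back.frame_rate == 8.0
        assert back.construct.name == end6.name

    def test_unequal_columns_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text(
            "frame\ttime_s\tdonor\tacceptor\n0\t0.0\t1.0\t2.0\n1\t1.0\t1.0\n")
        (tmp_path / "manifest.yaml").write_text(
            "traces:\n- file: bad.tsv\n  frame_rate: 1.0\n")
        with pytest.raises(ValueError, match="bad.tsv"):
            ns.read_traces(tmp_path / "manifest.yaml")

    def test_missing_file_rejected(self, tmp_path):
        (tmp_path / "manifest.yaml").write_text(
            "traces:\n- file: ghost.tsv\n  frame_rate: 1.0\n")
        with pytest.raises(FileNotFoundError, match="ghost.tsv"):
            ns.read_traces(tmp_path / "manifest.yaml")

    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _trace([1.0, 2.0], [1.0])


class TestPhotobleach:
    def test_clean_single_drop(self):
        total = np.r_[np.full(50, 100.0), np.full(50, 10.0)]
        t = _trace(total * 0.5, total * 0.5)
        call = ns.detect_photobleach(t)
        assert call.accepted and call.n_drops == 1 and call.bleach_frame == 50

    def test_two_drops_rejected(self):
        total = np.r_[np.full(40, 100.0), np.full(30, 60.0), np.full(30, 10.0)]
        t = _trace(total * 0.5, total * 0.5)
        call = ns.detect_photobleach(t)
        assert not call.accepted and call.n_drops == 2

    def test_noisy_drop_located_within_one_frame(self):
        rng = np.random.default_rng(4)
        total = np.r_[np.full(60, 100.0), np.full(60, 10.0)]
        total = total + rng.normal(0, 5.0, total.size)
        t = _trace(total * 0.6, total * 0.4)
        call = ns.detect_photobleach(t)
        assert call.accepted
        assert abs(call.bleach_frame - 60) <= 1

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ns.detect_photobleach(_trace(np.ones(5), np.ones(5)))

    def test_donor_vs_acceptor_channel_attribution(self):
        # acceptor vanishes, donor takes over -> total unchanged until the
        # donor itself bleaches; only that drop appears in the total
        donor = np.r_[np.full(40, 40.0), np.full(30, 100.0), np.full(30, 5.0)]
        acceptor = np.r_[np.full(40, 60.0), np.full(60, 2.0)]
        call = ns.detect_photobleach(_trace(donor, acceptor))
        assert call.accepted and call.channel == "donor" and call.bleach_frame == 70


class TestBackgroundAndFret:
    def _bleached_trace(self):
        donor = np.r_[np.full(60, 120.0), np.full(40, 20.0)]
        acceptor = np.r_[np.full(60, 80.0), np.full(40, 30.0)]
        return _trace(donor, acceptor)

    def test_background_means_subtracted(self):
        t = self._bleached_trace()
        call = ns.detect_photobleach(t)
        corr = ns.subtract_background(t, call)
        assert corr.donor[0] == pytest.approx(100.0)
        assert corr.acceptor[0] == pytest.approx(50.0)
        # post-bleach segment centered on zero
        assert np.mean(corr.donor[call.bleach_frame:]) == pytest.approx(0.0, abs=1e-9)

    def test_subtraction_requires_accepted_bleach(self):
        t = self._bleached_trace()
        with pytest.raises(ValueError):
            ns.subtract_background(t, ns.BleachCall(None, None, 0, False))

    def test_fret_through_background_contract(self):
        t = self._bleached_trace()
        call = ns.detect_photobleach(t)
        fret = ns.compute_fret(ns.subtract_background(t, call), call)
        assert fret.fret[0] == pytest.approx(50.0 / 150.0, abs=1e-9)
        assert not fret.valid_mask[call.bleach_frame:].any()

    def test_fret_limits(self):
        f = ns.compute_fret(_trace(np.full(20, 100.0), np.zeros(20)))
        assert np.all(f.fret[f.valid_mask] == 0.0)
        f = ns.compute_fret(_trace(np.full(20, 70.0), np.full(20, 70.0)))
        assert np.all(f.fret[f.valid_mask] == 0.5)

    def test_nonpositive_total_masked(self):
        donor = np.array([50.0] * 15 + [-1.0] + [50.0] * 15)
        acceptor = np.array([50.0] * 15 + [0.5] + [50.0] * 15)
        f = ns.compute_fret(_trace(donor, acceptor))
        assert not f.valid_mask[15]

    @given(k=st.floats(min_value=0.1, max_value=50.0))
    @settings(deadline=None, max_examples=25)
    def test_fret_scale_invariance(self, k):
        donor = np.linspace(10, 100, 30)
        acceptor = np.linspace(90, 5, 30)
        f1 = ns.compute_fret(_trace(donor, acceptor))
        f2 = ns.compute_fret(_trace(k * donor, k * acceptor))
        np.testing.assert_allclose(f1.fret, f2.fret, atol=1e-12)


class TestMedianFilter:
    def test_examples(self):
        assert list(ns.median_filter([0, 0, 1, 0, 0], 3)) == [0, 0, 0, 0, 0]
        np.testing.assert_allclose(ns.median_filter([5.0, 1.0, 1.0, 1.0], 3),
                                   [3.0, 1.0, 1.0, 1.0])
        const = np.full(10, 0.7)
        np.testing.assert_array_equal(ns.median_filter(const, 5), const)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ns.median_filter([1.0, 2.0], 2)

    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=3,
                    max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_monotone_preserved(self, values):
        y = np.sort(np.asarray(values))
        out = ns.median_filter(y, 3)
        assert np.all(np.diff(out) >= -1e-12)


class TestPopulationGate:
    @pytest.mark.parametrize("name,fret,keep", [
        ("H2A/H2A", 0.6, True),
        ("H2A/H2A", 0.15, False),
        ("H2B/H2B", 0.12, True),
        ("H2B/H2B", 0.05, False),
    ])
    def test_octamer_gates(self, name, fret, keep):
        assert ns.select_population(fret, ns.get_construct(name)) is keep

    def test_dna_labeled_window(self, end6):
        assert ns.select_population(0.6, end6, (0.3, 1.0))
        assert not ns.select_population(0.2, end6, (0.3, 1.0))


class TestIntensityRatioAndEnsemble:
    def test_unchanged_channels(self):
        t = _trace(np.full(40, 50.0), np.full(40, 30.0))
        assert ns.intensity_ratio(t, 20, 10) == (1.0, 1.0)

    def test_donor_enhancement_recovered(self, end6, calibration):
        p = ns.SimulationParams(noise_sd=0.0, bleach_rate=0.0,
                                pause_mean_tau=60.0, seed=3)
        trace, truth = ns.simulate_remodeling_trace(end6, p, calibration)
        b = truth.binding_frame
        d, a = ns.intensity_ratio(trace, b, window=min(10, b))
        assert d == pytest.approx(1.1, abs=1e-9)
        assert a == pytest.approx(1.0, abs=1e-9)

    def test_no_before_window(self):
        t = _trace(np.full(30, 50.0), np.full(30, 30.0))
        with pytest.raises(ValueError):
            ns.intensity_ratio(t, 0, 10)

    def test_normalize_affine(self):
        y = np.linspace(100, 40, 80)
        out = ns.normalize_ensemble(y)
        assert out[:10].mean() == pytest.approx(1.0, abs=0.05)
        assert out[-10:].mean() == pytest.approx(0.0, abs=0.05)

    def test_normalize_degenerate(self):
        with pytest.raises(ValueError):
            ns.normalize_ensemble(np.full(50, 3.0))

    def test_sum_singles_matches_ensemble_decay(self):
        """Summed single-molecule acceptor decays reproduce the analytic
        ensemble exponential within Monte-Carlo error."""
        rng = np.random.default_rng(9)
        n, T, tau = 500, 120, 30.0
        times = rng.exponential(tau, n)
        traces = []
        for t_off in times:
            a = np.where(np.arange(T) < t_off, 80.0, 0.0)
            traces.append(_trace(np.full(T, 20.0), a))
        ensemble = ns.sum_singles(traces) / (n * 80.0)
        expected = np.exp(-np.arange(T) / tau)
        assert np.max(np.abs(ensemble - expected)) < 4.0 / np.sqrt(n)


class TestBackgroundIdempotence:
    def test_second_subtraction_is_noop(self):
        rng = np.random.default_rng(2)
        donor = np.r_[np.full(80, 100.0), np.full(40, 15.0)] + rng.normal(0, 2, 120)
        acceptor = np.r_[np.full(80, 60.0), np.full(40, 8.0)] + rng.normal(0, 2, 120)
        t = _trace(donor, acceptor)
        call = ns.detect_photobleach(t)
        once = ns.subtract_background(t, call)
        twice = ns.subtract_background(once, call)
        np.testing.assert_allclose(once.donor, twice.donor, atol=1e-9)
        # post-bleach mean within 2 SE of zero by construction
        post = once.donor[call.bleach_frame:]
        assert abs(post.mean()) < 2 * post.std() / np.sqrt(post.size) + 1e-9
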