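"""Segmentation, averaging, caffeine response and derived metrics."""
import numpy as np
import pytest

from cahandling import (
    CaffeineTransient,
    CaTransient,
    EmptyResultError,
    NoiseSpec,
    NoReleaseWarning,
    Protocol,
    Segment,
    UndefinedResultError,
    average_transients,
    cell_area_shortening,
    detect_caffeine_transient,
    detect_transients,
    fractional_release,
    make_shortening_stack,
    recovery_fraction_time,
    render_fluorescence,
    simulate_myocyte,
    MyocyteParams,
)


def _calibrated(trace):
    ca, sat = trace.calibrate()
    return trace.time, ca, sat


class TestDetectTransients:
    def test_anchored_mode_finds_one_segment_per_beat(self, trace_clean_short):
        t, ca, sat = _calibrated(trace_clean_short)
        segs = detect_transients(t, ca, trace_clean_short.stimulus_times,
                                 trace_clean_short.caffeine_onset, sat=sat)
        assert len(segs) == 8

    def test_prominence_mode_agrees_with_anchored_on_clean_trace(self, trace_clean_short):
        t, ca, sat = _calibrated(trace_clean_short)
        anchored = detect_transients(t, ca, trace_clean_short.stimulus_times,
                                     trace_clean_short.caffeine_onset)
        blind = detect_transients(t, ca, None, trace_clean_short.caffeine_onset)
        assert len(blind) == len(anchored) == 8
        dt = float(np.median(np.diff(t)))
        for a, b in zip(anchored, blind):
            assert abs(a.peak_time - b.peak_time) <= dt + 1e-12

    def test_flat_trace_raises_with_diagnostics(self):
        with pytest.raises(EmptyResultError, match="threshold"):
            detect_transients(np.arange(0, 5, 1e-3), np.full(5000, 0.1))

    def test_beats_overlapping_caffeine_window_excluded(self, trace_clean_short):
        t, ca, _ = _calibrated(trace_clean_short)
        # pretend caffeine started mid-train: beats whose segment would
        # cross the guarded window (onset - 0.25 s) are dropped
        segs = detect_transients(t, ca, trace_clean_short.stimulus_times,
                                 caffeine_onset=3.6)
        assert len(segs) == 4
        assert all(s.stim_time + s.time[-1] <= 3.35 for s in segs)


class TestAverageTransients:
    @staticmethod
    def _identical_segments(n=5):
        t = np.arange(-0.05, 0.5, 1e-3)
        ca = np.where(t < 0, 0.1, 0.1 + 0.5 * np.exp(-5 * np.maximum(t, 0)))
        return [Segment(time=t.copy(), ca=ca.copy(), stim_time=float(k)) for k in range(n)]

    def test_average_of_identical_segments_is_the_segment(self):
        segs = self._identical_segments()
        cat = average_transients(segs, discard_first_n=2)
        single = average_transients(segs[:3], discard_first_n=2)
        np.testing.assert_allclose(cat.ca, single.ca, rtol=1e-12)
        assert cat.n_averaged == 3

    def test_metrics_on_exponential_recovery(self):
        segs = self._identical_segments()
        cat = average_transients(segs, discard_first_n=0)
        assert cat.diastolic == pytest.approx(0.1, rel=1e-9)
        assert cat.systolic == pytest.approx(0.6, rel=1e-3)
        # tau = 0.2 s -> t90 = -tau ln(0.1)
        assert cat.t_recovery_90 == pytest.approx(-0.2 * np.log(0.1), rel=1e-3)

    def test_averaging_shrinks_metric_noise_like_sqrt_n(self):
        rng = np.random.default_rng(0)
        t = np.arange(-0.05, 0.5, 1e-3)
        clean = np.where(t < 0, 0.1, 0.1 + 0.5 * np.exp(-5 * np.maximum(t, 0)))

        def systolic(n, trial):
            segs = [
                Segment(time=t, ca=clean + rng.normal(0, 0.05, t.size), stim_time=0.0)
                for _ in range(n)
            ]
            return average_transients(segs, discard_first_n=0).systolic

        s1 = np.std([systolic(1, i) for i in range(40)])
        s50 = np.std([systolic(50, i) for i in range(40)])
        assert s50 < s1 / np.sqrt(50) * 2.5  # ~1/sqrt(n), generous MC slack

    def test_discarding_all_segments_raises(self):
        with pytest.raises(Exception, match="no beats left"):
            average_transients(self._identical_segments(2), discard_first_n=5)


class TestRecoveryFractionTime:
    @pytest.mark.parametrize(
        "fraction, expected",
        [(0.9, -0.2 * np.log(0.1)), (0.5, 0.2 * np.log(2))],
    )
    def test_closed_form_on_exponential(self, fraction, expected):
        t = np.arange(0, 2, 1e-3)
        y = 0.1 + 0.9 * np.exp(-t / 0.2)
        got = recovery_fraction_time(t, y, fraction=fraction, baseline=0.1, peak=1.0)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_non_crossing_plateau_returns_sentinel(self):
        t = np.arange(0, 1, 1e-3)
        y = np.full(t.size, 1.0)
        y[0] = 2.0
        assert np.isnan(recovery_fraction_time(t, y, fraction=0.9, baseline=0.0, peak=2.0))


class TestCaffeineTransient:
    @staticmethod
    def _caffeine_only_amplitude(params):
        proto = Protocol(n_beats=0, caffeine_onset=5.0, duration=15.0)
        sim = simulate_myocyte(params, proto)
        tr = render_fluorescence(sim, noise=NoiseSpec(0.0, 0))
        t, ca, _ = _calibrated(tr)
        return detect_caffeine_transient(t, ca, 5.0)

    def test_amplitude_matches_release_extrusion_closed_form(self, default_params):
        # with release at k_caff and removal at lam = k_ncx/beta the free-Ca
        # peak is (s0/beta) * k/(k-lam) * (e^(-lam t*) - e^(-k t*)),
        # t* = ln(k/lam)/(k-lam): slightly below s0/beta because NCX
        # extrudes while the SR is still emptying
        p = default_params
        cafft = self._caffeine_only_amplitude(p)
        k, lam = p.k_caff, p.k_ncx / p.beta
        t_star = np.log(k / lam) / (k - lam)
        expected = (p.sr_init / p.beta) * k / (k - lam) * (
            np.exp(-lam * t_star) - np.exp(-k * t_star)
        )
        assert cafft.amplitude == pytest.approx(expected, rel=1e-3)
        assert cafft.resting == pytest.approx(p.c_rest, rel=1e-6)

    def test_amplitude_within_5pc_of_sr_load_when_release_fast(self):
        p = MyocyteParams(k_caff=100.0)
        cafft = self._caffeine_only_amplitude(p)
        assert cafft.amplitude == pytest.approx(p.sr_init / p.beta, rel=0.05)

    def test_empty_sr_warns_and_reports_zero(self, default_params):
        p = MyocyteParams(sr_init=0.0)
        sim = simulate_myocyte(p, Protocol(n_beats=0, caffeine_onset=5.0, duration=10.0))
        tr = render_fluorescence(sim, noise=NoiseSpec(0.0, 0))
        t, ca, _ = _calibrated(tr)
        with pytest.warns(NoReleaseWarning):
            cafft = detect_caffeine_transient(t, ca, 5.0)
        assert cafft.amplitude == 0.0

    def test_resting_equals_diastolic_after_long_recovery(self, default_params):
        # with a long quiescent gap the pre-caffeine level relaxes to c_rest
        proto = Protocol(n_beats=4, caffeine_onset=13.0, duration=20.0)
        sim = simulate_myocyte(default_params, proto)
        tr = render_fluorescence(sim, noise=NoiseSpec(0.0, 0))
        t, ca, _ = _calibrated(tr)
        cafft = detect_caffeine_transient(t, ca, 13.0)
        assert cafft.resting == pytest.approx(default_params.c_rest, abs=1e-4)


class TestFractionalRelease:
    @staticmethod
    def _cat(amp):
        t = np.arange(-0.05, 0.3, 1e-3)
        return CaTransient(time=t, ca=np.full(t.size, 0.1), diastolic=0.1,
                           systolic=0.1 + amp, amplitude=amp, t_recovery_90=0.1,
                           n_averaged=1)

    @staticmethod
    def _cafft(amp):
        return CaffeineTransient(resting=0.1, peak=0.1 + amp, amplitude=amp,
                                 peak_time=0.0, recovery_time=np.arange(3),
                                 recovery_ca=np.zeros(3))

    def test_definition(self):
        assert fractional_release(self._cat(0.6), self._cafft(0.8)) == pytest.approx(0.75)

    def test_zero_cat_amplitude_gives_zero(self):
        assert fractional_release(self._cat(0.0), self._cafft(0.8)) == 0.0

    def test_zero_cafft_amplitude_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            fractional_release(self._cat(0.5), self._cafft(0.0))

    def test_above_one_allowed_but_flagged(self):
        with pytest.warns(UserWarning, match="> 1"):
            v = fractional_release(self._cat(1.0), self._cafft(0.5))
        assert v == pytest.approx(2.0)


class TestCellAreaShortening:
    def test_round_trip_recovers_requested_shortening(self):
        stack = make_shortening_stack(n_frames=40, rest_area_px=10000,
                                      peak_shortening=0.10, noise_sd=5.0, seed=1)
        res = cell_area_shortening(stack)
        assert res.shortening == pytest.approx(0.10, abs=0.02)

    def test_distractor_blob_ignored(self):
        stack = make_shortening_stack(n_frames=20, peak_shortening=0.10)
        with_blob = stack.copy()
        with_blob[:, 2:12, 2:12] = 1000.0  # small second bright object
        a = cell_area_shortening(stack).shortening
        b = cell_area_shortening(with_blob).shortening
        assert b == pytest.approx(a, abs=1e-6)

    def test_empty_frame_becomes_nan_with_warning(self):
        stack = make_shortening_stack(n_frames=10, peak_shortening=0.0)
        stack[3] = 0.0
        with pytest.warns(UserWarning, match="empty mask"):
            res = cell_area_shortening(stack, threshold=500.0)
        assert np.isnan(res.areas[3]) and np.isfinite(res.shortening)
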