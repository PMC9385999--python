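"""ABR analysis: windows, RMS, onsets, thresholds, latencies, equal-SL symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otokit import abr, synth
from otokit._common import InvalidWindowError, NoSignalError, suffix_threshold

FS = 24414.0


def make_rec(samples, fs=FS, level=80.0):
    return abr.ABRRecording(
        samples=np.asarray(samples, dtype=float),
        sampling_rate_hz=fs,
        stimulus_frequency_hz=8000.0,
        level_db_spl=level,
    )


def kernel_rec(peak_ms=2.0, width_ms=0.3, amp=1.0, duration_ms=12.8, fs=FS):
    t = np.arange(int(round(duration_ms * fs / 1000.0))) * 1000.0 / fs
    return make_rec(amp * synth.peak_kernel(t, peak_ms, width_ms), fs=fs)


class TestWindows:
    @pytest.mark.parametrize(
        "onset,early,late",
        [
            (1.5, (1.5, 3.0), (3.0, 9.0)),
            (2.2, (2.2, 3.7), (3.7, 9.7)),
            (0.0, (0.0, 1.5), (1.5, 7.5)),
        ],
    )
    def test_window_arithmetic(self, onset, early, late):
        w = abr.build_windows(onset)
        assert w.early == pytest.approx(early)
        assert w.late == pytest.approx(late)
        assert w.early[1] - w.early[0] == pytest.approx(1.5)
        assert w.late[1] - w.late[0] == pytest.approx(6.0)
        assert w.late[0] == w.early[1]

    def test_negative_onset_rejected(self):
        with pytest.raises(ValueError):
            abr.build_windows(-0.1)


class TestRMS:
    def test_zero_signal(self):
        rec = make_rec(np.zeros(400))
        assert abr.rms_amplitude(rec, (1.0, 5.0)) == 0.0

    def test_sine_closed_form(self):
        # 2 kHz sine over exactly 8 cycles in a 4 ms window at 2 kHz-aligned fs
        fs = 32000.0
        t = np.arange(int(fs * 0.012)) / fs
        rec = make_rec(3.0 * np.sin(2 * np.pi * 2000.0 * t), fs=fs)
        got = abr.rms_amplitude(rec, (0.0, 4.0))
        assert got == pytest.approx(3.0 / np.sqrt(2.0), rel=1e-6)

    def test_constant_signal(self):
        rec = make_rec(np.full(400, -0.7))
        assert abr.rms_amplitude(rec, (2.0, 6.0)) == pytest.approx(0.7)

    def test_empty_window_rejected(self):
        rec = make_rec(np.ones(400))
        with pytest.raises(InvalidWindowError):
            abr.rms_amplitude(rec, (5.0, 5.0))

    def test_half_open_window_excludes_end_sample(self):
        fs = 1000.0  # 1 ms per sample
        x = np.zeros(20)
        x[5] = 1.0
        rec = make_rec(x, fs=fs)
        assert abr.rms_amplitude(rec, (0.0, 5.0)) == 0.0
        assert abr.rms_amplitude(rec, (5.0, 6.0)) == pytest.approx(1.0)


class TestOnsetDetection:
    def test_onset_precedes_kernel_peak(self):
        rec = kernel_rec(peak_ms=2.0, width_ms=0.3)
        onset = abr.detect_wave1_onset(rec, template_latency_ms=2.0)
        assert 1.4 <= onset <= 1.8

    def test_pure_noise_falls_back_to_template(self):
        # bounded uniform noise never exceeds twice its own SD (2*0.577 > 1)
        rng = np.random.default_rng(0)
        rec = make_rec(rng.uniform(-1.0, 1.0, 400))
        assert abr.detect_wave1_onset(rec, template_latency_ms=2.0) == 2.0

    def test_translation_equivariance(self):
        a = kernel_rec(peak_ms=2.0)
        b = kernel_rec(peak_ms=2.5)
        oa = abr.detect_wave1_onset(a, 2.0)
        ob = abr.detect_wave1_onset(b, 2.0)
        assert ob - oa == pytest.approx(0.5, abs=2000.0 / FS)

    def test_all_zero_raises_no_signal(self):
        with pytest.raises(NoSignalError):
            abr.detect_wave1_onset(make_rec(np.zeros(400)), 2.0)


class TestIOFunction:
    def test_attenuated_points_shift_on_level_axis(self, wt_series_8k, attenuated_series_8k):
        io0 = abr.build_io(wt_series_8k)
        io20 = abr.build_io(attenuated_series_8k)
        a0 = dict(io0.points)
        a20 = dict(io20.points)
        for level in (30.0, 50.0, 70.0, 90.0):
            assert a20[level] == pytest.approx(a0[level - 20.0], rel=1e-6)

    def test_amplitude_monotone_in_level_without_noise(self, wt_series_8k):
        amps = abr.build_io(wt_series_8k).amplitudes
        assert all(b >= a for a, b in zip(amps, amps[1:]))

    def test_single_level_rejected(self, wt_series_8k):
        single = abr.ABRLevelSeries(recordings=(wt_series_8k.recordings[-1],))
        with pytest.raises(ValueError):
            abr.build_io(single)


class TestThreshold:
    def test_threshold_above_which_criterion_always_holds(self):
        io = abr.IOFunction(
            points=((10, 0.02), (20, 0.05), (30, 0.09), (40, 0.15), (50, 0.40)),
            window_kind="early",
        )
        assert abr.estimate_threshold(io).threshold_db == 30.0

    def test_not_reached_when_top_level_fails(self):
        io = abr.IOFunction(points=((10, 0.02), (90, 0.05)), window_kind="early")
        res = abr.estimate_threshold(io)
        assert not res.reached

    def test_non_monotonic_uses_suffix_rule(self):
        io = abr.IOFunction(
            points=((10, 0.15), (20, 0.05), (30, 0.2), (40, 0.3)), window_kind="early"
        )
        assert abr.estimate_threshold(io).threshold_db == 20.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 0.5, allow_nan=False), min_size=1, max_size=12),
        st.floats(0.01, 0.4),
    )
    def test_matches_brute_force_suffix_scan(self, amps, criterion):
        levels = [10.0 * (i + 1) for i in range(len(amps))]
        got = suffix_threshold(levels, [a > criterion for a in amps])
        # brute force: smallest level whose strict suffix all passes, provided
        # the top level itself passes
        expected = None
        if amps[-1] > criterion:
            candidates = [
                L
                for i, L in enumerate(levels)
                if all(a > criterion for a in amps[i + 1 :])
            ]
            expected = min(candidates)
        assert got == expected


class TestPeakLatencies:
    def test_six_peaks_recovered_within_one_sample(self):
        """With non-overlapping peaks the detected latencies equal the generator
        peak times to sample precision (overlapping kernels legitimately pull
        composite peaks off tau, so narrow widths isolate the detector)."""
        params = synth.default_abr_params(8000.0, seed=7, peak_widths_ms=(0.12,) * 6)
        series = synth.simulate_abr_series(params)
        onsets = abr._chained_onsets(series, 1.5)
        lats = abr.peak_latencies(series.at_level(80.0), onsets[80.0][1])
        expected = [i + 0.02 * 10.0 for i in synth.DEFAULT_LATENCY_INTERCEPTS_MS]
        assert sorted(lats.latencies_ms) == [1, 2, 3, 4, 5, 6]
        for wave, tau in zip(range(1, 7), expected):
            assert lats.latencies_ms[wave] == pytest.approx(tau, abs=1000.0 / FS)

    def test_detected_peaks_match_oversampled_composite(self, wt_series_8k):
        """With the default (overlapping) widths, each detected peak matches the
        true local maximum of the composite waveform within one sample."""
        rec = wt_series_8k.at_level(80.0)
        onsets = abr._chained_onsets(wt_series_8k, 1.5)
        lats = abr.peak_latencies(rec, onsets[80.0][1])
        # analytic composite on a 100x finer grid as the oracle
        fine_t = np.arange(0, 12.8, 1000.0 / FS / 100.0)
        composite = np.zeros_like(fine_t)
        params = synth.default_abr_params(8000.0, seed=7)
        for intercept, slope, amp, width in zip(
            params.peak_latency_intercepts_ms,
            params.peak_latency_slopes_ms_per_db,
            params.peak_amplitude_params,
            params.peak_widths_ms,
        ):
            tau = intercept + slope * 10.0
            composite += amp.amplitude(80.0) * synth.peak_kernel(fine_t, tau, width)
        for wave, lat in lats.latencies_ms.items():
            near = (fine_t > lat - 0.4) & (fine_t < lat + 0.4)
            true_peak = fine_t[near][np.argmax(composite[near])]
            assert lat == pytest.approx(true_peak, abs=1000.0 / FS)

    def test_single_peak_waveform(self):
        rec = kernel_rec(peak_ms=2.0)
        lats = abr.peak_latencies(rec, abr.build_windows(1.5))
        assert list(lats.latencies_ms) == [1]
        assert not lats.warning

    def test_flat_signal_warns_empty(self):
        rec = make_rec(np.zeros(400))
        lats = abr.peak_latencies(rec, abr.build_windows(1.5))
        assert lats.latencies_ms == {}
        assert lats.warning


class TestThresholdShift:
    def test_flatness_is_max_minus_min(self):
        mk = lambda v: abr.ThresholdResult(v, 0.1)
        wt = {4000.0: mk(40.0), 8000.0: mk(40.0), 16000.0: mk(30.0), 32000.0: mk(40.0)}
        ds = {4000.0: mk(55.0), 8000.0: mk(57.0), 16000.0: mk(46.0), 32000.0: mk(55.0)}
        res = abr.threshold_shift(wt, ds)
        assert res.shifts_db[8000.0] == pytest.approx(17.0)
        assert res.flatness_db == pytest.approx(2.0)

    def test_identical_groups_zero_shift(self):
        mk = lambda v: abr.ThresholdResult(v, 0.1)
        wt = {8000.0: mk(40.0), 16000.0: mk(30.0)}
        res = abr.threshold_shift(wt, dict(wt))
        assert set(res.shifts_db.values()) == {0.0}

    def test_unreached_threshold_excluded_with_flag(self):
        mk = lambda v: abr.ThresholdResult(v, 0.1)
        wt = {8000.0: mk(40.0), 16000.0: mk(30.0)}
        ds = {8000.0: mk(50.0), 16000.0: abr.ThresholdResult(None, 0.1)}
        res = abr.threshold_shift(wt, ds)
        assert res.excluded == (16000.0,)
        assert list(res.shifts_db) == [8000.0]

    @pytest.mark.parametrize("atten", [5.0, 10.0, 15.0, 20.0])
    def test_simulated_attenuation_recovered_to_grid(self, atten):
        """Noise-free conductive loss recovers as a shift equal to a rounded
        onto the 10 dB level grid, at every stimulus frequency."""
        freqs = (4000.0, 8000.0, 16000.0, 32000.0)
        for freq in freqs:
            s0 = synth.simulate_abr_series(synth.default_abr_params(freq, seed=3))
            sa = synth.simulate_abr_series(
                synth.default_abr_params(freq, attenuation_db=atten, seed=3)
            )
            t0 = abr.estimate_threshold(abr.build_io(s0)).threshold_db
            ta = abr.estimate_threshold(abr.build_io(sa)).threshold_db
            shift = ta - t0
            assert shift in (10.0 * np.floor(atten / 10.0), 10.0 * np.ceil(atten / 10.0))
            assert abs(shift - atten) <= 10.0


class TestEqualSL:
    def test_grid_aligned_attenuation_gives_identical_latencies(
        self, wt_series_8k, attenuated_series_8k
    ):
        """A 20 dB loss on a 10 dB grid: equal sensation level maps both groups
        onto the same effective intensity, so wave I-V latencies coincide."""
        wt_thr = abr.estimate_threshold(abr.build_io(wt_series_8k))
        ds_thr = abr.estimate_threshold(abr.build_io(attenuated_series_8k))
        assert ds_thr.threshold_db - wt_thr.threshold_db == 20.0
        cmp = abr.equal_sl_latency_compare(
            wt_series_8k, wt_thr, attenuated_series_8k, ds_thr, sl_db=30.0
        )
        assert cmp.comparison_level_db - cmp.reference_level_db == 20.0
        diffs = cmp.table["difference_ms"].to_numpy()[:5]
        assert np.all(np.abs(diffs) <= 1000.0 / FS)

    def test_same_absolute_level_latencies_longer_under_attenuation(
        self, wt_series_8k, attenuated_series_8k
    ):
        on_wt = abr._chained_onsets(wt_series_8k, 1.5)
        on_ds = abr._chained_onsets(attenuated_series_8k, 1.5)
        lw = abr.peak_latencies(wt_series_8k.at_level(80.0), on_wt[80.0][1])
        ld = abr.peak_latencies(attenuated_series_8k.at_level(80.0), on_ds[80.0][1])
        for wave in range(1, 6):
            assert ld.latencies_ms[wave] > lw.latencies_ms[wave]

    def test_sl_beyond_grid_names_limiting_series(self, wt_series_8k, attenuated_series_8k):
        wt_thr = abr.estimate_threshold(abr.build_io(wt_series_8k))
        ds_thr = abr.estimate_threshold(abr.build_io(attenuated_series_8k))
        with pytest.raises(ValueError, match="comparison"):
            abr.equal_sl_latency_compare(
                wt_series_8k, wt_thr, attenuated_series_8k, ds_thr, sl_db=50.0
            )
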