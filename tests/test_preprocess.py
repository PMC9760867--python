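"""Preprocessing pipeline: resampling, windowing, peak detection, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgbeats.preprocess import (
    InsufficientBeatsError,
    PreprocessParams,
    Window,
    WindowAnalysis,
    detect_r_peaks,
    extract_segments,
    nominal_period,
    normalize_window,
    preprocess_record,
    resample_signal,
    split_windows,
)


class TestResample:
    def test_360_to_125_length(self):
        assert resample_signal(np.zeros(3600), 360, 125).size == 1250

    def test_identity_when_rates_equal(self, rng):
        x = rng.random(500)
        assert np.allclose(resample_signal(x, 125, 125), x)

    def test_sinusoid_keeps_its_frequency(self):
        t = np.arange(3600) / 360.0
        x = np.sin(2 * np.pi * 5.0 * t)
        y = resample_signal(x, 360, 125)
        freqs = np.fft.rfftfreq(y.size, d=1 / 125.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(y)))]
        assert abs(peak - 5.0) < 0.2

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            resample_signal(np.array([1.0]), 360, 125)


class TestSplitWindows:
    def test_partial_tail_discarded(self):
        wins = split_windows(np.arange(3000.0), fs=125, window_s=10)
        assert len(wins) == 2
        assert all(w.samples.size == 1250 for w in wins)

    def test_exact_single_window(self):
        assert len(split_windows(np.zeros(1250), fs=125)) == 1

    def test_windows_tile_the_kept_prefix(self, rng):
        x = rng.random(4100)
        wins = split_windows(x, fs=125)
        tiled = np.concatenate([w.samples for w in wins])
        assert np.array_equal(tiled, x[:tiled.size])
        assert [w.start_index for w in wins] == [0, 1250, 2500]


class TestNormalize:
    def test_minmax_arithmetic(self):
        w = normalize_window(Window(np.array([2.0, 4.0, 6.0])))
        assert np.allclose(w.samples, [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self, rng):
        x = rng.random(100)
        x[0], x[1] = 0.0, 1.0
        w = normalize_window(Window(x))
        assert np.allclose(w.samples, x)

    def test_constant_window_maps_to_zeros(self):
        w = normalize_window(Window(np.full(10, 5.0)))
        assert np.all(w.samples == 0.0)


class TestDetectRPeaks:
    def test_single_bump(self):
        x = np.exp(-0.5 * ((np.arange(1250) - 500) / 5.0) ** 2)
        assert list(detect_r_peaks(Window(x))) == [500]

    def test_subthreshold_secondary_bump_excluded(self):
        # raw amplitudes 0.95 and 0.85 normalize to 1.0 and 0.894 < 0.9
        i = np.arange(1250)
        x = (0.95 * np.exp(-0.5 * ((i - 300) / 5.0) ** 2)
             + 0.85 * np.exp(-0.5 * ((i - 900) / 5.0) ** 2))
        w = normalize_window(Window(x))
        assert list(detect_r_peaks(w)) == [300]

    def test_refractory_keeps_larger_of_close_pair(self):
        i = np.arange(1250)
        x = (0.98 * np.exp(-0.5 * ((i - 500) / 4.0) ** 2)
             + 1.00 * np.exp(-0.5 * ((i - 510) / 4.0) ** 2))
        w = normalize_window(Window(x))
        peaks = detect_r_peaks(w, fs=125.0)
        assert len(peaks) == 1
        assert abs(peaks[0] - 510) <= 2

    def test_flatline_yields_no_peaks(self):
        assert detect_r_peaks(Window(np.zeros(1250))).size == 0

    def test_against_generator_ground_truth(self, clean_record):
        cfg, rec = clean_record
        x = resample_signal(rec.lead(0), rec.fs, 125.0)
        ann = np.array([int(round(i * 125.0 / rec.fs))
                        for i, _ in rec.annotations])
        detected = []
        for w in split_windows(x, 125.0):
            wn = normalize_window(w)
            detected.extend(w.start_index + p for p in detect_r_peaks(wn))
        detected = np.asarray(detected)
        prefix = (x.size // 1250) * 1250
        ann_in = ann[ann < prefix]
        hits = sum(np.min(np.abs(detected - a)) <= 2 for a in ann_in)
        assert hits / ann_in.size >= 0.99
        false = sum(np.min(np.abs(ann - d)) > 2 for d in detected)
        assert 1 - false / detected.size >= 0.99


class TestNominalPeriod:
    def test_median_of_intervals(self):
        assert nominal_period([100, 225, 350, 480]) == 125

    def test_equally_spaced(self):
        assert nominal_period(np.arange(0, 1000, 110)) == 110

    def test_even_interval_count_uses_midpoint_mean(self):
        assert nominal_period([0, 100, 220]) == 110

    def test_fewer_than_two_peaks_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            nominal_period([500])

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=50,
                    unique=True))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_median(self, peaks):
        peaks = sorted(peaks)
        diffs = sorted(b - a for a, b in zip(peaks, peaks[1:]))
        m = len(diffs)
        expected = (diffs[m // 2] if m % 2
                    else (diffs[m // 2 - 1] + diffs[m // 2]) / 2)
        assert nominal_period(peaks) == expected


class TestExtractSegments:
    def _window(self, n=1250):
        rng = np.random.default_rng(0)
        x = rng.random(n)
        x[0], x[1] = 0.0, 1.0
        return normalize_window(Window(x))

    def test_pad_tail_is_zero(self):
        w = self._window()
        analysis = WindowAnalysis(r_peaks=np.array([100, 400]), T=125.0)
        segs = extract_segments(w, analysis, segment_length=187)
        span = round(1.2 * 125)  # 150 signal samples + 37 zeros
        for s in segs:
            assert s.values.size == 187
            assert np.array_equal(s.values[:span],
                                  w.samples[s.peak_index:s.peak_index + span])
            assert np.all(s.values[span:] == 0.0)

    def test_truncation_when_span_exceeds_length(self):
        w = self._window()
        analysis = WindowAnalysis(r_peaks=np.array([10]), T=200.0)
        segs = extract_segments(w, analysis, segment_length=187)
        assert segs[0].values.size == 187
        assert np.all(segs[0].values == w.samples[10:197])

    def test_span_crossing_window_end_padded(self):
        w = self._window()
        analysis = WindowAnalysis(r_peaks=np.array([1200]), T=125.0)
        (seg,) = extract_segments(w, analysis, segment_length=187)
        assert np.array_equal(seg.values[:50], w.samples[1200:])
        assert np.all(seg.values[50:] == 0.0)

    def test_values_stay_in_unit_interval(self):
        w = self._window()
        analysis = WindowAnalysis(r_peaks=np.array([0, 300, 600]), T=150.0)
        for s in extract_segments(w, analysis):
            assert s.values.min() >= 0.0 and s.values.max() <= 1.0


class TestPreprocessRecord:
    def test_beat_yield_on_clean_record(self, clean_record):
        cfg, rec = clean_record
        ds = preprocess_record(rec)
        assert len(ds) >= 0.9 * cfg.n_beats
        assert ds.segments.shape[1] == 187
        assert ds.segments.min() >= 0.0 and ds.segments.max() <= 1.0

    def test_short_record_gives_empty_dataset(self):
        from ecgbeats.dataio import EcgRecord
        rec = EcgRecord(np.zeros((100, 1)), fs=125.0)
        assert len(preprocess_record(rec)) == 0

    def test_flatline_window_contributes_nothing(self):
        from ecgbeats.dataio import EcgRecord
        rec = EcgRecord(np.zeros((2500, 1)), fs=125.0)
        assert len(preprocess_record(rec)) == 0

    def test_deterministic(self, noisy_record):
        _, rec = noisy_record
        a, b = preprocess_record(rec), preprocess_record(rec)
        assert np.array_equal(a.segments, b.segments)
        assert np.array_equal(a.peak_indices, b.peak_indices)
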