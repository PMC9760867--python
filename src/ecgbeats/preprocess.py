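"""Beat segmentation pipeline: resample, window, normalize, detect R peaks,
estimate the nominal period, and cut fixed-length zero-padded segments.

The pipeline is deliberately denoising-free: the raw signal is resampled to a
working rate (125 Hz by default), split into non-overlapping 10 s windows,
min-max normalized per window, R-peak candidates are the local maxima at or
above 0.9 of the normalized maximum, the nominal heartbeat period ``T`` is
the median R-R interval of the window, and each beat segment spans
``[peak, peak + round(1.2*T))``, zero-padded (or truncated) to a fixed length
``L`` (187 samples by default).

All indices are 0-based; spans are half-open.  The pipeline contains no
randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .dataio import EcgRecord, SegmentDataset

logger = logging.getLogger(__name__)

DEFAULT_FS = 125.0
DEFAULT_WINDOW_S = 10.0
DEFAULT_THRESHOLD = 0.9
DEFAULT_SEGMENT_LENGTH = 187
DEFAULT_REFRACTORY_S = 0.2
SPAN_FACTOR = 1.2


@dataclass
class Window:
    """One normalized analysis window with its offset into the parent signal."""

    samples: np.ndarray
    start_index: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("empty window")


@dataclass
class WindowAnalysis:
    """Detected R peaks (window-local indices) and the nominal period T."""

    r_peaks: np.ndarray
    T: float | None

    def __post_init__(self):
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if self.r_peaks.size > 1 and not np.all(np.diff(self.r_peaks) > 0):
            raise ValueError("r_peaks must be strictly increasing")


@dataclass
class PreprocessParams:
    fs_out: float = DEFAULT_FS
    window_s: float = DEFAULT_WINDOW_S
    threshold: float = DEFAULT_THRESHOLD
    segment_length: int = DEFAULT_SEGMENT_LENGTH
    refractory_s: float = DEFAULT_REFRACTORY_S
    lead: int = 0


def resample_signal(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited (Fourier) resampling to ``round(len(x) * fs_out / fs_in)``
    samples."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    n_out = int(round(x.size * fs_out / fs_in))
    if fs_in == fs_out:
        return x.copy()
    return scipy.signal.resample(x, n_out)


def split_windows(x: np.ndarray, fs: float,
                  window_s: float = DEFAULT_WINDOW_S) -> list[Window]:
    """Non-overlapping consecutive windows; a final partial window is dropped."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(x, dtype=float)
    n = int(round(window_s * fs))
    return [Window(x[s:s + n], start_index=s)
            for s in range(0, x.size - n + 1, n)]


def normalize_window(w: Window) -> Window:
    """Min-max normalize to [0, 1]; a constant window maps to all zeros."""
    lo, hi = w.samples.min(), w.samples.max()
    if hi == lo:
        return Window(np.zeros_like(w.samples), w.start_index)
    return Window((w.samples - lo) / (hi - lo), w.start_index)


def detect_r_peaks(w: Window, threshold: float = DEFAULT_THRESHOLD,
                   fs: float = DEFAULT_FS,
                   refractory_s: float = DEFAULT_REFRACTORY_S) -> np.ndarray:
    """R-peak candidates: local maxima (first difference changes sign + to -)
    whose normalized amplitude is at or above ``threshold``.

    Candidates closer together than the refractory interval are pruned,
    keeping the larger; this guards against double detections on a single
    noisy QRS complex.  Flat-topped maxima report their first sample.
    """
    x = w.samples
    sign = np.sign(np.diff(x))
    # carry the sign of the last nonzero difference across flat runs
    nz = np.flatnonzero(sign)
    if nz.size == 0:
        return np.array([], dtype=np.int64)
    fill = np.where(sign != 0, np.arange(sign.size), 0)
    np.maximum.accumulate(fill, out=fill)
    sign = sign[fill]
    rising_to_falling = (sign[:-1] > 0) & (sign[1:] < 0)
    cand = np.flatnonzero(rising_to_falling) + 1
    # a plateau maximum reports its first plateau sample
    starts = []
    for c in cand:
        while c > 0 and x[c - 1] == x[c]:
            c -= 1
        starts.append(int(c))
    cand = np.asarray(starts, dtype=np.int64)
    cand = cand[x[cand] >= threshold] if cand.size else cand
    if cand.size == 0:
        return np.array([], dtype=np.int64)
    min_gap = refractory_s * fs
    kept: list[int] = []
    for c in cand:
        if kept and c - kept[-1] < min_gap:
            if x[c] > x[kept[-1]]:
                kept[-1] = int(c)
        else:
            kept.append(int(c))
    return np.asarray(kept, dtype=np.int64)


class InsufficientBeatsError(ValueError):
    """Fewer than two R peaks: the nominal period is undefined."""


def nominal_period(r_peaks) -> float:
    """Median of successive R-R intervals, in samples.

    With an even number of intervals the median is the mean of the two
    central values.
    """
    r_peaks = np.asarray(r_peaks)
    if r_peaks.size < 2:
        raise InsufficientBeatsError(
            f"need >= 2 peaks to estimate the period, got {r_peaks.size}")
    return float(np.median(np.diff(r_peaks)))


@dataclass
class BeatSegment:
    """One fixed-length beat segment plus provenance for labeling."""

    values: np.ndarray
    label: int = -1
    window_start: int = 0
    peak_index: int = 0          # window-local R-peak index

    @property
    def global_peak_index(self) -> int:
        return self.window_start + self.peak_index


def extract_segments(w: Window, analysis: WindowAnalysis,
                     segment_length: int = DEFAULT_SEGMENT_LENGTH,
                     span_factor: float = SPAN_FACTOR) -> list[BeatSegment]:
    """Cut ``[p, p + round(span_factor*T))`` for each R peak ``p``; zero-pad
    (or truncate) to ``segment_length``.  Spans crossing the window end use
    the available samples and pad the rest."""
    if analysis.T is None or analysis.T <= 0:
        return []
    span = int(round(span_factor * analysis.T))
    segments = []
    for p in analysis.r_peaks:
        chunk = w.samples[p:p + span][:segment_length]
        values = np.zeros(segment_length)
        values[:chunk.size] = chunk
        segments.append(BeatSegment(values=values, window_start=w.start_index,
                                    peak_index=int(p)))
    return segments


def analyze_window(w: Window, params: PreprocessParams) -> WindowAnalysis:
    peaks = detect_r_peaks(w, threshold=params.threshold, fs=params.fs_out,
                           refractory_s=params.refractory_s)
    T = None
    if peaks.size >= 2:
        T = nominal_period(peaks)
    return WindowAnalysis(r_peaks=peaks, T=T)


def preprocess_record(record: EcgRecord,
                      params: PreprocessParams | None = None) -> SegmentDataset:
    """Full pipeline: resample -> window -> normalize -> detect -> period ->
    extract.  Windows with fewer than two detected peaks contribute nothing.
    """
    params = params or PreprocessParams()
    x = resample_signal(record.lead(params.lead), record.fs, params.fs_out)
    windows = split_windows(x, params.fs_out, params.window_s)
    if not windows:
        logger.warning("record shorter than one %.0f s window; empty dataset",
                       params.window_s)
        return SegmentDataset(np.empty((0, params.segment_length)),
                              np.empty(0, dtype=np.int64), fs=params.fs_out,
                              peak_indices=np.empty(0, dtype=np.int64))
    all_segments: list[BeatSegment] = []
    for w in windows:
        wn = normalize_window(w)
        analysis = analyze_window(wn, params)
        if analysis.T is None:
            continue
        all_segments.extend(
            extract_segments(wn, analysis, params.segment_length))
    if not all_segments:
        return SegmentDataset(np.empty((0, params.segment_length)),
                              np.empty(0, dtype=np.int64), fs=params.fs_out,
                              peak_indices=np.empty(0, dtype=np.int64))
    seg = np.stack([s.values for s in all_segments])
    peaks = np.array([s.global_peak_index for s in all_segments])
    labels = np.full(len(all_segments), -1, dtype=np.int64)
    return SegmentDataset(seg, labels, fs=params.fs_out, peak_indices=peaks,
                          meta={"source_fs": record.fs})
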