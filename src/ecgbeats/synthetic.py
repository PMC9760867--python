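"""Synthetic single-lead ECG generator with known beat-level ground truth.

Beats are sums of Gaussian bumps (P, QRS, T), one template per AAMI class:

* N — P wave, narrow dominant QRS, T wave;
* S — no P wave, slightly narrow QRS, and a shortened preceding R-R
  interval (premature coupling);
* V — wide, high-amplitude QRS, no P wave;
* F — component-wise average of the N and V shapes (fusion beat);
* Q — a broad flat-topped pulse (generalized Gaussian, exponent 4).

A record is a concatenation of per-beat waveforms at a configurable heart
rate with R-R jitter, plus sinusoidal baseline wander (0.3 Hz), sinusoidal
powerline interference (50 Hz) and white Gaussian noise.  Each annotation
marks the sample of the beat's QRS maximum with the class symbol.  Identical
configurations (same seed) produce bit-identical records.

This is a test harness, not a physiological simulator: waveforms are
analytically simple so that detector and classifier behavior can be checked
against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataio import CLASS_NAMES, EcgRecord, SegmentDataset, label_segments
from .preprocess import PreprocessParams, preprocess_record

#: Training-set class fractions the generator mirrors by default (heavily
#: imbalanced: majority N > 80%, rarest F < 1%).
DEFAULT_PROPORTIONS = (0.828, 0.025, 0.066, 0.007, 0.074)


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump: center offset (s, relative to QRS), width (s),
    amplitude (QRS-normalized units), and shape exponent (2 = Gaussian,
    larger = flatter top)."""

    center: float
    width: float
    amplitude: float
    power: float = 2.0


@dataclass(frozen=True)
class BeatTemplate:
    """Per-class beat morphology as a list of wave components.

    The QRS component must strictly dominate every other component in
    absolute amplitude so the waveform maximum marks the R peak.
    """

    class_label: str
    waves: tuple[WaveComponent, ...]
    qrs_index: int = 1
    rr_scale: float = 1.0        # preceding R-R shortening (premature beats)

    def __post_init__(self):
        qrs = self.waves[self.qrs_index]
        for i, wave in enumerate(self.waves):
            if i != self.qrs_index and abs(wave.amplitude) >= abs(qrs.amplitude):
                raise ValueError(
                    f"QRS must dominate: component {i} of template "
                    f"{self.class_label!r} has |amp| >= QRS")

    @property
    def qrs(self) -> WaveComponent:
        return self.waves[self.qrs_index]


def default_templates() -> dict[str, BeatTemplate]:
    n_waves = (WaveComponent(-0.20, 0.025, 0.15),   # P
               WaveComponent(0.0, 0.018, 1.00),     # QRS
               WaveComponent(0.30, 0.060, 0.30))    # T
    # QRS amplitudes stay within ~10% of each other across classes: the
    # detector thresholds at 0.9 of the per-window maximum, so a much taller
    # class would mask its neighbors' R peaks within the same window.
    v_waves = (WaveComponent(-0.20, 0.025, 0.0),    # no P
               WaveComponent(0.0, 0.050, 1.05),     # wide, slightly taller QRS
               WaveComponent(0.35, 0.070, -0.25))   # discordant T
    f_waves = tuple(WaveComponent((a.center + b.center) / 2,
                                  (a.width + b.width) / 2,
                                  (a.amplitude + b.amplitude) / 2)
                    for a, b in zip(n_waves, v_waves))
    return {
        "N": BeatTemplate("N", n_waves),
        "S": BeatTemplate("S", (WaveComponent(-0.20, 0.025, 0.0),
                                WaveComponent(0.0, 0.014, 0.97),
                                WaveComponent(0.28, 0.055, 0.25)),
                          rr_scale=0.7),
        "V": BeatTemplate("V", v_waves),
        "F": BeatTemplate("F", f_waves),
        "Q": BeatTemplate("Q", (WaveComponent(-0.18, 0.02, 0.0),
                                WaveComponent(0.0, 0.045, 0.95, power=4.0),
                                WaveComponent(0.30, 0.05, 0.15))),
    }


@dataclass(frozen=True)
class NoiseSpec:
    baseline_amp: float = 0.05      # 0.3 Hz sinusoidal baseline wander
    powerline_amp: float = 0.02     # 50 Hz powerline interference
    white_sigma: float = 0.02       # white Gaussian noise

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic record."""

    n_beats: int = 1000
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    fs: float = 360.0
    hr_mean_bpm: float = 75.0
    rr_jitter_frac: float = 0.08
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.fs < 50:
            raise ValueError("fs must be >= 50 Hz")
        if self.hr_mean_bpm <= 0:
            raise ValueError("hr_mean_bpm must be positive")
        if not 0.0 <= self.rr_jitter_frac <= 0.3:
            raise ValueError("rr_jitter_frac must be in [0, 0.3]")
        p = np.asarray(self.class_proportions, dtype=float)
        if p.size != len(CLASS_NAMES) or np.any(p < 0):
            raise ValueError("class_proportions must be 5 non-negative reals")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")


BASELINE_HZ = 0.3
POWERLINE_HZ = 50.0
#: Fraction of the beat interval at which the QRS center sits.
QRS_PHASE = 0.35


def synth_beat(template: BeatTemplate, rr: float, fs: float,
               rng: np.random.Generator | None = None,
               amplitude_jitter: float = 0.0) -> np.ndarray:
    """One beat waveform of ``round(rr * fs)`` samples.

    The QRS center sits at ``QRS_PHASE * rr`` so the preceding P wave fits in
    the same beat; the waveform's global maximum falls on the QRS center
    sample (+/- 1 sample).  ``amplitude_jitter`` scales the non-QRS
    components by ``1 + jitter * U(-1, 1)`` per wave.
    """
    if rr <= 0 or fs <= 0:
        raise ValueError("rr and fs must be positive")
    n = int(round(rr * fs))
    t = np.arange(n) / fs - QRS_PHASE * rr
    y = np.zeros(n)
    for i, wave in enumerate(template.waves):
        amp = wave.amplitude
        if amplitude_jitter and rng is not None and i != template.qrs_index:
            amp *= 1.0 + amplitude_jitter * rng.uniform(-1.0, 1.0)
        y += amp * np.exp(-np.abs((t - wave.center) / wave.width) ** wave.power)
    return y


def qrs_sample(template: BeatTemplate, rr: float, fs: float) -> int:
    """Sample index of the QRS center within a beat from :func:`synth_beat`."""
    return int(np.argmin(np.abs(np.arange(int(round(rr * fs))) / fs
                                - QRS_PHASE * rr - template.qrs.center)))


def synth_record(config: SyntheticConfig,
                 templates: dict[str, BeatTemplate] | None = None) -> EcgRecord:
    """Generate a full annotated record from ``config``.

    Beat classes are a seeded multinomial draw from the configured
    proportions; annotation indices mark QRS maxima.
    """
    templates = templates or default_templates()
    rng = np.random.default_rng(config.seed)
    classes = rng.choice(len(CLASS_NAMES), size=config.n_beats,
                         p=np.asarray(config.class_proportions))
    rr_mean = 60.0 / config.hr_mean_bpm
    pieces: list[np.ndarray] = []
    annotations: list[tuple[int, str]] = []
    start = 0
    for c in classes:
        sym = CLASS_NAMES[c]
        tpl = templates[sym]
        rr = rr_mean * tpl.rr_scale * (
            1.0 + config.rr_jitter_frac * rng.uniform(-1.0, 1.0))
        rr = max(rr, 0.25)
        beat = synth_beat(tpl, rr, config.fs, rng, amplitude_jitter=0.1)
        annotations.append((start + int(np.argmax(beat)), sym))
        pieces.append(beat)
        start += beat.size
    x = np.concatenate(pieces)
    t = np.arange(x.size) / config.fs
    noise = config.noise
    if noise.baseline_amp:
        x = x + noise.baseline_amp * np.sin(
            2 * math.pi * BASELINE_HZ * t + rng.uniform(0, 2 * math.pi))
    if noise.powerline_amp:
        x = x + noise.powerline_amp * np.sin(
            2 * math.pi * POWERLINE_HZ * t + rng.uniform(0, 2 * math.pi))
    if noise.white_sigma:
        x = x + rng.normal(0.0, noise.white_sigma, size=x.size)
    return EcgRecord(x[:, None], config.fs, annotations,
                     channel_names=("synthetic",))


def synth_dataset(config: SyntheticConfig,
                  segment_length: int = 187,
                  params: PreprocessParams | None = None) -> SegmentDataset:
    """Record generation + the full preprocessing pipeline + ground-truth
    labeling; returns only labeled segments."""
    if segment_length < 16:
        raise ValueError("segment_length must be >= 16")
    record = synth_record(config)
    params = params or PreprocessParams(segment_length=segment_length)
    if params.segment_length != segment_length:
        raise ValueError("segment_length disagrees with params")
    ds = preprocess_record(record, params)
    ds = label_segments(ds, record)
    ds.meta["synthetic_config_seed"] = config.seed
    return ds
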