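"""Records, annotations, AAMI class mapping, and dataset persistence.

An :class:`EcgRecord` holds one or more waveform channels at a fixed sampling
rate together with beat annotations (sample index + single-character symbol).
Symbols follow the MIT-BIH convention and are grouped into the five AAMI EC57
superclasses N/S/V/F/Q; non-beat symbols (rhythm changes, artifacts) are
ignored.

Supported on-disk formats:

* package CSV dialect: ``<stem>.csv`` with a ``# fs: <Hz>`` comment line and
  ``sample_index,value`` rows, plus a sidecar ``<stem>.ann.csv`` with
  ``sample_index,symbol`` rows;
* a minimal WFDB-compatible pair: text ``.hea`` header + 16-bit little-endian
  ``.dat`` signal, with annotations as rdann-style text (``.ann``: sample
  index and symbol per line);
* segment datasets: HDF5 container (groups ``/segments``, ``/labels``,
  ``/meta``) plus a flat CSV export, one row per segment with the label in
  the last column.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

CLASS_NAMES = ("N", "S", "V", "F", "Q")
N_CLASSES = 5
IGNORE = "ignore"

#: MIT-BIH beat symbol -> AAMI EC57 superclass.
AAMI_CLASS_MAP: dict[str, str] = {
    # N: normal, bundle-branch blocks, atrial/nodal escape
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    # S: atrial premature family, nodal/supraventricular premature
    "A": "S", "a": "S", "J": "S", "S": "S",
    # V: premature ventricular contraction, ventricular escape
    "V": "V", "E": "V",
    # F: fusion of ventricular and normal
    "F": "F",
    # Q: paced, fusion of paced and normal, unclassifiable
    "/": "Q", "f": "Q", "Q": "Q",
}

LABEL_OF_CLASS = {c: i for i, c in enumerate(CLASS_NAMES)}

DATASET_LAYOUT_VERSION = 1


def map_symbol(symbol: str, class_map: dict[str, str] | None = None) -> str:
    """Map a beat annotation symbol to its AAMI class, or ``"ignore"``.

    Total and pure: any symbol outside the recognized beat set (rhythm-change
    markers, noise flags, ...) maps to ``"ignore"``.
    """
    cmap = AAMI_CLASS_MAP if class_map is None else class_map
    return cmap.get(symbol, IGNORE)


@dataclass
class EcgRecord:
    """Raw waveform(s) + sampling rate + beat annotations."""

    signals: np.ndarray            # (n_samples, n_channels)
    fs: float
    annotations: list[tuple[int, str]] = field(default_factory=list)
    channel_names: tuple[str, ...] = ("ch0",)

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] < self.signals.shape[1]:
            # accept (channels, samples) input from careless callers
            self.signals = self.signals.T
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.signals.shape[0]
        for idx, sym in self.annotations:
            if not 0 <= idx < n:
                raise IndexError(
                    f"annotation at sample {idx} outside signal of length {n}")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, i: int = 0) -> np.ndarray:
        return self.signals[:, i]


@dataclass
class SegmentDataset:
    """Fixed-length normalized beat segments with integer class labels.

    ``labels`` uses 0..4 for N/S/V/F/Q and -1 for unlabeled segments.
    ``peak_indices`` are the detected R-peak positions in the resampled
    (working-rate) coordinate system, used to associate annotations.
    """

    segments: np.ndarray                       # (n, L)
    labels: np.ndarray                         # (n,) int
    fs: float = 125.0
    peak_indices: np.ndarray | None = None     # (n,) int, global indices
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.segments.shape[0] != self.labels.shape[0]:
            raise ValueError("segments and labels disagree in length")
        if self.peak_indices is not None:
            self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def segment_length(self) -> int:
        return self.segments.shape[1]

    @property
    def class_counts(self) -> np.ndarray:
        labeled = self.labels[self.labels >= 0]
        return np.bincount(labeled, minlength=N_CLASSES)[:N_CLASSES]

    def subset(self, idx) -> "SegmentDataset":
        pk = None if self.peak_indices is None else self.peak_indices[idx]
        return SegmentDataset(self.segments[idx], self.labels[idx],
                              fs=self.fs, peak_indices=pk,
                              meta=dict(self.meta))


# --------------------------------------------------------------------------
# record I/O
# --------------------------------------------------------------------------

def write_record_csv(record: EcgRecord, path) -> Path:
    """Write lead 0 as ``sample_index,value`` CSV + ``.ann.csv`` sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs: {record.fs:g}\n")
        fh.write("sample_index,value\n")
        for i, v in enumerate(record.lead(0)):
            fh.write(f"{i},{v:.9g}\n")
    ann_path = path.with_suffix(".ann.csv")
    with open(ann_path, "w") as fh:
        fh.write("sample_index,symbol\n")
        for idx, sym in record.annotations:
            fh.write(f"{idx},{sym}\n")
    return path


def _read_record_csv(path: Path) -> EcgRecord:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# fs:"):
            raise ValueError(f"{path}: missing '# fs:' header line")
        fs = float(first.split(":", 1)[1])
        body = fh.read()
    df = pd.read_csv(io.StringIO(body))
    signal = df["value"].to_numpy(dtype=float)[:, None]
    annotations: list[tuple[int, str]] = []
    ann_path = path.with_suffix(".ann.csv")
    if ann_path.exists():
        ann = pd.read_csv(ann_path, dtype={"symbol": str})
        annotations = [(int(i), str(s))
                       for i, s in zip(ann["sample_index"], ann["symbol"])]
    return EcgRecord(signal, fs, annotations, channel_names=("ch0",))


def write_record_wfdb(record: EcgRecord, stem) -> Path:
    """Write a minimal WFDB-compatible record (format 16, gain 200 adu/mV).

    The annotation file is rdann-style text (``sample_index symbol`` per
    line), not the binary .atr encoding.
    """
    stem = Path(stem)
    name = stem.name
    nc = record.signals.shape[1]
    gain, fmt = 200.0, 16
    adus = np.clip(np.rint(record.signals * gain), -32768, 32767).astype("<i2")
    with open(stem.with_suffix(".hea"), "w") as fh:
        fh.write(f"{name} {nc} {record.fs:g} {record.n_samples}\n")
        for c in range(nc):
            cname = record.channel_names[c] if c < len(record.channel_names) else f"ch{c}"
            fh.write(f"{name}.dat {fmt} {gain:g}(0)/mV 16 0 0 0 0 {cname}\n")
    adus.reshape(-1, nc).tofile(stem.with_suffix(".dat"))
    with open(stem.with_suffix(".ann"), "w") as fh:
        for idx, sym in record.annotations:
            fh.write(f"{idx} {sym}\n")
    return stem.with_suffix(".hea")


def _read_record_wfdb(header_path: Path) -> EcgRecord:
    stem = header_path.with_suffix("")
    lines = [ln for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    nc, fs, n_samples = int(head[1]), float(head[2]), int(head[3])
    names, gains = [], []
    for ln in lines[1:1 + nc]:
        parts = ln.split()
        if int(parts[1]) != 16:
            raise ValueError(f"{header_path}: only format 16 is supported")
        gains.append(float(parts[2].split("(")[0].split("/")[0]))
        names.append(parts[-1])
    raw = np.fromfile(stem.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_samples * nc:
        raise ValueError(f"{stem}.dat: expected {n_samples * nc} samples, "
                         f"found {raw.size}")
    signals = raw.reshape(-1, nc).astype(float) / np.asarray(gains)
    annotations: list[tuple[int, str]] = []
    ann_path = stem.with_suffix(".ann")
    if ann_path.exists():
        for ln in ann_path.read_text().splitlines():
            if ln.strip():
                idx, sym = ln.split()
                annotations.append((int(idx), sym))
    return EcgRecord(signals, fs, annotations, channel_names=tuple(names))


def read_record(path) -> EcgRecord:
    """Read a record from the CSV dialect or the minimal WFDB pair."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such record: {path}")
    if path.suffix == ".hea":
        return _read_record_wfdb(path)
    if path.suffix == ".csv":
        return _read_record_csv(path)
    raise ValueError(f"unrecognized record format: {path} "
                     "(expected .hea or .csv)")


# --------------------------------------------------------------------------
# segment labeling
# --------------------------------------------------------------------------

def label_segments(ds: SegmentDataset, record: EcgRecord,
                   class_map: dict[str, str] | None = None,
                   max_distance_s: float = 0.15) -> SegmentDataset:
    """Label each segment with the class of its nearest annotation.

    Annotation indices are converted from the record's native rate to the
    dataset's working rate.  A segment keeps only a label whose annotation
    lies within ``max_distance_s`` of its detected R peak; segments with no
    annotation in range, or whose nearest annotation is a non-beat symbol,
    are dropped.
    """
    if ds.peak_indices is None:
        raise ValueError("dataset carries no peak indices; cannot label")
    beats = [(int(round(idx * ds.fs / record.fs)), map_symbol(sym, class_map))
             for idx, sym in record.annotations]
    beats = [(i, c) for i, c in beats if c != IGNORE]
    if not beats:
        return ds.subset(np.zeros(len(ds), dtype=bool))
    ann_idx = np.array([i for i, _ in beats])
    ann_lab = np.array([LABEL_OF_CLASS[c] for _, c in beats])
    order = np.argsort(ann_idx)
    ann_idx, ann_lab = ann_idx[order], ann_lab[order]

    gate = max_distance_s * ds.fs
    pos = np.searchsorted(ann_idx, ds.peak_indices)
    keep = np.zeros(len(ds), dtype=bool)
    labels = np.full(len(ds), -1, dtype=np.int64)
    for k, (p, j) in enumerate(zip(ds.peak_indices, pos)):
        cands = [c for c in (j - 1, j) if 0 <= c < len(ann_idx)]
        if not cands:
            continue
        best = min(cands, key=lambda c: abs(int(ann_idx[c]) - int(p)))
        if abs(int(ann_idx[best]) - int(p)) <= gate:
            keep[k] = True
            labels[k] = ann_lab[best]
    out = ds.subset(keep)
    out.labels = labels[keep]
    return out


# --------------------------------------------------------------------------
# dataset persistence
# --------------------------------------------------------------------------

def save_dataset(ds: SegmentDataset, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("segments", data=ds.segments)
        f.create_dataset("labels", data=ds.labels)
        if ds.peak_indices is not None:
            f.create_dataset("peak_indices", data=ds.peak_indices)
        meta = f.create_group("meta")
        meta.attrs["layout_version"] = DATASET_LAYOUT_VERSION
        meta.attrs["fs"] = ds.fs
        meta.attrs["json"] = json.dumps(ds.meta)
    return path


def load_dataset(path) -> SegmentDataset:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = int(f["meta"].attrs["layout_version"])
            if version != DATASET_LAYOUT_VERSION:
                raise ValueError(
                    f"{path}: dataset layout version {version} found, "
                    f"expected {DATASET_LAYOUT_VERSION}")
            ds = SegmentDataset(
                segments=f["segments"][...],
                labels=f["labels"][...],
                fs=float(f["meta"].attrs["fs"]),
                peak_indices=(f["peak_indices"][...]
                              if "peak_indices" in f else None),
                meta=json.loads(f["meta"].attrs["json"]),
            )
        return ds
    except OSError as e:
        raise OSError(f"{path}: not a readable dataset container ({e})") from e


def export_dataset_csv(ds: SegmentDataset, path) -> Path:
    """Flat CSV export: one row per segment, label in the last column."""
    path = Path(path)
    cols = {f"s{i}": ds.segments[:, i] for i in range(ds.segment_length)}
    cols["label"] = ds.labels
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def mark_split(ds: SegmentDataset, split: str) -> SegmentDataset:
    """Tag a dataset as 'train' or 'test' (protocol metadata)."""
    out = replace(ds)
    out.meta = dict(ds.meta, split=split)
    return out
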