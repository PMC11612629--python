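"""Reading, filtering, segmenting, and splitting single-channel EEG records.

Supports the Bonn University plain-text dialect (one ASCII integer per line,
4,097 samples at 173.61 Hz) and EDF scalp recordings (e.g. CHB-MIT at 256 Hz).
Preprocessing follows the standard clinical recipe: a fourth-order Butterworth
bandpass (0.5-70 Hz) followed by a 50 Hz mains notch, then segmentation into
fixed-length overlapping windows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

BONN_FS = 173.61
#: class labels used throughout: healthy, interictal, ictal, or unlabeled
LABELS = ("healthy", "interictal", "ictal")
UNLABELED = "unlabeled"


@dataclass
class EegRecord:
    """One channel of EEG samples (microvolts) with provenance."""

    samples: np.ndarray
    fs: float
    label: str = UNLABELED
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class SegmentSet:
    """Fixed-length windows cut from one or more records, with aligned labels."""

    segments: np.ndarray  # (n_segments, window_len)
    labels: np.ndarray  # (n_segments,) of str
    window_len: int
    overlap: int
    fs: float

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        if self.segments.size == 0:
            self.segments = self.segments.reshape(0, self.window_len)
        self.labels = np.asarray(self.labels)
        if self.segments.shape[0] != self.labels.shape[0]:
            raise ValueError("labels must align one-to-one with segment rows")
        if self.segments.shape[1] != self.window_len and self.segments.shape[0] > 0:
            raise ValueError("every row must have exactly window_len entries")
        if not (0 <= self.overlap < self.window_len):
            raise ValueError("need 0 <= overlap < window_len")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def stride(self) -> int:
        return self.window_len - self.overlap


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass + notch filtering parameters."""

    band_low: float = 0.5
    band_high: float = 70.0
    order: int = 4
    notch_freq: float = 50.0
    notch_q: float = 30.0

    def validate(self, fs: float) -> "FilterSpec":
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        high = self.band_high
        nyq = fs / 2.0
        if high >= nyq:
            # Bonn's 173.61 Hz puts 70 Hz close to Nyquist already; for lower
            # rates clamp the upper edge rather than refuse the record.
            high = 0.99 * nyq
            if high <= self.band_low:
                raise ValueError(
                    f"band [{self.band_low}, {self.band_high}] Hz infeasible at fs={fs}"
                )
        return replace(self, band_high=high)


def read_bonn_record(path: str | Path, label: str = UNLABELED) -> EegRecord:
    """Read a Bonn-dialect record: plain text, one number per line.

    Blank lines are skipped.  A non-numeric line raises ``ValueError`` naming
    the offending line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno} is not numeric: {line!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    return EegRecord(np.array(values), fs=BONN_FS, label=label, source_id=path.name)


def read_edf_records(
    path: str | Path, channel_selector: Sequence[str] | str = "all"
) -> list[EegRecord]:
    """Read an EDF file into one record per selected channel.

    Labels are left ``unlabeled``; seizure annotations are attached by the
    caller (see :func:`read_annotation_sidecar` / :func:`label_by_intervals`).
    Samples are returned in microvolts.
    """
    import mne  # heavy import, only needed for EDF sources

    path = Path(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    if channel_selector == "all":
        wanted = available
    else:
        wanted = list(channel_selector)
        missing = [ch for ch in wanted if ch not in available]
        if missing:
            raise KeyError(
                f"channel(s) {missing} not in {path.name}; available: {available}"
            )
    data = raw.get_data(picks=wanted) * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    return [
        EegRecord(data[i], fs=fs, source_id=f"{path.name}:{ch}")
        for i, ch in enumerate(wanted)
    ]


def read_annotation_sidecar(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Parse a seizure-interval sidecar: ``record_id<TAB>start_s<TAB>end_s``."""
    intervals: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno} needs 3 tab-separated fields")
            rec, start, end = parts[0], float(parts[1]), float(parts[2])
            intervals.setdefault(rec, []).append((start, end))
    return intervals


def label_by_intervals(
    segset: SegmentSet,
    seizure_intervals: Sequence[tuple[float, float]],
    background_label: str = "interictal",
    min_fraction: float = 0.5,
) -> SegmentSet:
    """Label each segment ictal when >= ``min_fraction`` of its samples fall
    inside an annotated seizure interval, else ``background_label``.

    Segment i is assumed to start at sample ``i * stride`` of the source
    record (the convention of :func:`segment_record`).
    """
    n = len(segset)
    labels = np.array([background_label] * n, dtype=object)
    starts = np.arange(n) * segset.stride / segset.fs
    seg_dur = segset.window_len / segset.fs
    for i, t0 in enumerate(starts):
        t1 = t0 + seg_dur
        covered = 0.0
        for s, e in seizure_intervals:
            covered += max(0.0, min(t1, e) - max(t0, s))
        if covered / seg_dur >= min_fraction:
            labels[i] = "ictal"
    return SegmentSet(
        segset.segments, labels.astype(str), segset.window_len, segset.overlap, segset.fs
    )


def apply_filters(record: EegRecord, spec: FilterSpec | None = None) -> EegRecord:
    """Zero-phase Butterworth bandpass followed by a mains notch.

    Both stages run forward-backward (``sosfiltfilt`` / ``filtfilt``) so the
    features downstream see no phase distortion.  Length and fs are preserved.
    """
    spec = (spec or FilterSpec()).validate(record.fs)
    sos = signal.butter(
        spec.order, [spec.band_low, spec.band_high], btype="bandpass",
        fs=record.fs, output="sos",
    )
    x = signal.sosfiltfilt(sos, record.samples)
    if 0 < spec.notch_freq < record.fs / 2:
        b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=record.fs)
        x = signal.filtfilt(b, a, x)
    return EegRecord(x, fs=record.fs, label=record.label, source_id=record.source_id)


def segment_record(
    record: EegRecord, window_len: int = 1024, overlap: int = 64
) -> SegmentSet:
    """Cut a record into overlapping fixed-length windows.

    ``overlap`` is the number of shared samples between consecutive windows,
    so the stride is ``window_len - overlap``; windows start at
    0, stride, 2*stride, ... and a trailing partial window is discarded.
    """
    if not (0 <= overlap < window_len):
        raise ValueError("need 0 <= overlap < window_len")
    n = len(record)
    stride = window_len - overlap
    if window_len > n:
        warnings.warn(
            f"window_len {window_len} exceeds record length {n}; no segments",
            stacklevel=2,
        )
        return SegmentSet(
            np.empty((0, window_len)), np.empty(0, dtype=str), window_len, overlap, record.fs
        )
    n_seg = (n - window_len) // stride + 1
    idx = np.arange(n_seg)[:, None] * stride + np.arange(window_len)[None, :]
    return SegmentSet(
        record.samples[idx],
        np.array([record.label] * n_seg),
        window_len,
        overlap,
        record.fs,
    )


def concat_segment_sets(sets: Sequence[SegmentSet]) -> SegmentSet:
    """Stack segment sets that share window/overlap/fs parameters."""
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if (s.window_len, s.overlap, s.fs) != (first.window_len, first.overlap, first.fs):
            raise ValueError("segment sets have mismatched parameters")
    return SegmentSet(
        np.vstack([s.segments for s in sets]),
        np.concatenate([s.labels for s in sets]),
        first.window_len,
        first.overlap,
        first.fs,
    )


def split_segments(
    segset: SegmentSet,
    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05),
    seed: int = 0,
) -> tuple[SegmentSet, SegmentSet, SegmentSet]:
    """Stratified train/validation/test split.

    Per-label counts are floor allocations of the fractions; remainders are
    assigned in the order train -> val -> test.  Deterministic for a fixed
    seed; the three outputs are disjoint and their union is the input.
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    part_idx: list[list[int]] = [[], [], []]
    for lab in np.unique(segset.labels):
        idx = np.flatnonzero(segset.labels == lab)
        if idx.size < 3:
            raise ValueError(f"label {lab!r} has {idx.size} segments; cannot stratify")
        rng.shuffle(idx)
        counts = np.floor(fr * idx.size).astype(int)
        rem = idx.size - counts.sum()
        for j in range(rem):  # leftover goes train -> val -> test
            counts[j % 3] += 1
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for p in range(3):
            part_idx[p].extend(idx[offsets[p]:offsets[p + 1]])
    out = []
    for p in range(3):
        sel = np.sort(np.array(part_idx[p], dtype=int))
        out.append(
            SegmentSet(
                segset.segments[sel],
                segset.labels[sel],
                segset.window_len,
                segset.overlap,
                segset.fs,
            )
        )
    return out[0], out[1], out[2]


def save_segment_set(segset: SegmentSet, path: str | Path) -> None:
    """Write segments as CSV plus a JSON sidecar with the cut parameters."""
    path = Path(path)
    df = pd.DataFrame(segset.segments)
    df.insert(0, "label", segset.labels)
    df.to_csv(path, index=False)
    meta = {"window_len": segset.window_len, "overlap": segset.overlap, "fs": segset.fs}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_segment_set(path: str | Path) -> SegmentSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy(dtype=str)
    return SegmentSet(df.to_numpy(dtype=float), labels, meta["window_len"], meta["overlap"], meta["fs"])
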