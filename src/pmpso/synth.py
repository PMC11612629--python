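"""Synthetic EEG and labeled feature tables with known ground truth.

Surrogate single-channel EEG whose class identity is carried by band-power
composition and transient spike-wave content:

* ``healthy`` — alpha-dominant background rhythm, no spikes;
* ``interictal`` — mixed slow background with sporadic spike-wave
  transients;
* ``ictal`` — high-amplitude 2-4 Hz dominant rhythm with dense spiking.

These recipes emulate the gross spectral/transient contrasts of scalp EEG
classes, not physiological EEG; multi-channel structure, artifacts and
non-stationarity within a record are deliberately absent.

Also provides labeled Gaussian feature tables with planted informative
columns and rho-correlated redundant copies, for exercising the selector
against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .io import BONN_FS, EegRecord

_BAND_EDGES = {
    "delta": (0.5, 4.0),  # 0.5 not 0.1: keeps the synthesis filter well-conditioned
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 70.0),
}


@dataclass(frozen=True)
class SynthEegSpec:
    """Recipe for one surrogate EEG record."""

    class_label: str
    fs: float = BONN_FS
    n_samples: int = 4097
    band_amplitudes: dict = field(default_factory=dict)
    spike_rate: float = 0.0  # events / second
    spike_amplitude: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0


#: per-class default recipes (amplitudes in arbitrary microvolt-like units)
DEFAULT_CLASS_SPECS: dict[str, SynthEegSpec] = {
    "healthy": SynthEegSpec(
        class_label="healthy",
        band_amplitudes={"delta": 8, "theta": 7, "alpha": 24, "beta": 5, "gamma": 2},
        spike_rate=0.0,
        spike_amplitude=0.0,
        noise_sd=4.0,
    ),
    "interictal": SynthEegSpec(
        class_label="interictal",
        band_amplitudes={"delta": 13, "theta": 9, "alpha": 10, "beta": 6, "gamma": 2.5},
        spike_rate=1.2,
        spike_amplitude=75.0,
        noise_sd=5.0,
    ),
    "ictal": SynthEegSpec(
        class_label="ictal",
        band_amplitudes={"delta": 40, "theta": 14, "alpha": 6, "beta": 5, "gamma": 3},
        spike_rate=3.0,
        spike_amplitude=100.0,
        noise_sd=5.0,
    ),
}


def _band_noise(rng, n, fs, low, high):
    """Unit-variance noise band-limited to [low, high] Hz."""
    white = rng.standard_normal(n)
    high = min(high, 0.99 * fs / 2)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spike_wave(fs: float) -> np.ndarray:
    """One period of a 3 Hz biphasic spike-wave transient, unit peak."""
    n = max(int(round(fs / 3.0)), 4)
    t = np.arange(n) / n
    # sharp positive spike followed by a slow negative wave
    return np.sin(2 * np.pi * t) * np.hanning(n) * 2.0


def gen_eeg_record(spec: SynthEegSpec) -> EegRecord:
    """One surrogate record: summed band-limited noise + Poisson-timed
    spike-wave transients + white noise; bit-reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    x = np.zeros(spec.n_samples)
    for band, amp in spec.band_amplitudes.items():
        if amp <= 0:
            continue
        lo, hi = _BAND_EDGES[band]
        if hi >= spec.fs / 2 and lo >= 0.99 * spec.fs / 2:
            raise ValueError(f"band {band} infeasible at fs={spec.fs}")
        x += amp * _band_noise(rng, spec.n_samples, spec.fs, lo, hi)
    if spec.spike_rate > 0 and spec.spike_amplitude > 0:
        wave = _spike_wave(spec.fs) * spec.spike_amplitude
        duration = spec.n_samples / spec.fs
        n_events = rng.poisson(spec.spike_rate * duration)
        starts = rng.integers(0, max(spec.n_samples - wave.size, 1), size=n_events)
        for s in starts:
            end = min(s + wave.size, spec.n_samples)
            x[s:end] += wave[: end - s]
    if spec.noise_sd > 0:
        x += spec.noise_sd * rng.standard_normal(spec.n_samples)
    if not np.any(x):
        # degenerate all-zero spec: keep the record valid and exactly zero
        return EegRecord(np.zeros(spec.n_samples), spec.fs, spec.class_label,
                         f"synth-{spec.class_label}-{spec.seed}")
    return EegRecord(x, spec.fs, spec.class_label, f"synth-{spec.class_label}-{spec.seed}")


def gen_eeg_dataset(
    n_per_class: int,
    base_specs: dict[str, SynthEegSpec] | None = None,
    seed: int = 0,
    amplitude_jitter: float = 0.4,
    gain_jitter: float = 0.3,
) -> list[EegRecord]:
    """Class-balanced list of surrogate records with within-class variability.

    Two lognormal jitters act per record: ``amplitude_jitter`` perturbs each
    band amplitude independently (spectral-shape variability) and
    ``gain_jitter`` scales the whole record (electrode gain / impedance
    variability).  The global gain makes any single amplitude-dependent
    feature a weak classifier on its own while leaving relative spectral
    structure — hence multivariate separability — intact."""
    base_specs = base_specs or DEFAULT_CLASS_SPECS
    rng = np.random.default_rng(seed)
    records = []
    for label in sorted(base_specs):
        base = base_specs[label]
        for i in range(n_per_class):
            rec_seed = int(rng.integers(0, 2**31 - 1))
            gain = float(np.exp(rng.normal(0.0, gain_jitter))) if gain_jitter > 0 else 1.0
            amps = {
                b: a * gain * (float(np.exp(rng.normal(0.0, amplitude_jitter)))
                               if amplitude_jitter > 0 else 1.0)
                for b, a in base.band_amplitudes.items()
            }
            spec = SynthEegSpec(
                class_label=base.class_label,
                fs=base.fs,
                n_samples=base.n_samples,
                band_amplitudes=amps,
                spike_rate=base.spike_rate,
                spike_amplitude=base.spike_amplitude * gain,
                noise_sd=base.noise_sd * gain,
                seed=rec_seed,
            )
            records.append(gen_eeg_record(spec))
    return records


def write_bonn_dialect(records: Sequence[EegRecord], out_dir: str | Path) -> Path:
    """Write records as Bonn-dialect text files plus a labels CSV, so
    synthetic data flows through the identical reader path as real data."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        fname = f"synth{i:04d}.txt"
        np.savetxt(out_dir / fname, rec.samples, fmt="%.3f")
        rows.append({"file": fname, "label": rec.label, "fs": rec.fs})
    labels_path = out_dir / "labels.csv"
    pd.DataFrame(rows).to_csv(labels_path, index=False)
    return labels_path


@dataclass(frozen=True)
class SynthTableSpec:
    """Recipe for a labeled feature table with known ground truth."""

    n_samples: int = 300
    n_features: int = 8
    informative_idx: tuple[int, ...] = (0, 1, 2)
    effect_size: float = 2.0  # class-mean separation in noise-sd units
    redundant_pairs: tuple[tuple[int, int, float], ...] = ()  # (source, copy, rho)
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        copies = [c for _, c, _ in self.redundant_pairs]
        if set(copies) & set(self.informative_idx):
            raise ValueError("copy indices must be disjoint from informative_idx")
        if len(set(copies)) != len(copies):
            raise ValueError("duplicate copy indices")
        for _, _, rho in self.redundant_pairs:
            if abs(rho) > 1:
                raise ValueError("|rho| must be <= 1")


def gen_feature_table(spec: SynthTableSpec):
    """Gaussian table: informative columns get class-dependent means
    separated by ``effect_size`` (noise sd = 1), copy columns are
    rho-correlated duplicates of their source, everything else pure noise.

    Returns ``(DataFrame with columns f0..f{d-1}, labels array, truth)``
    where truth records the informative names and the pair map.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    labels = np.repeat(np.arange(spec.n_classes), math.ceil(n / spec.n_classes))[:n]
    rng.shuffle(labels)
    X = rng.standard_normal((n, d))
    for rank, j in enumerate(spec.informative_idx):
        # one-vs-rest contrasts: each informative column elevates a single
        # class, so informative columns stay mutually near-uncorrelated and
        # no single column separates all classes on its own
        target = rank % spec.n_classes
        X[:, j] += spec.effect_size * (labels == target)
    for src, copy, rho in spec.redundant_pairs:
        base = X[:, src]
        z = (base - base.mean()) / base.std()
        if abs(rho) == 1.0:
            X[:, copy] = base.copy() if rho > 0 else -base
        else:
            X[:, copy] = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    names = [f"f{j}" for j in range(d)]
    truth = {
        "informative": [names[j] for j in spec.informative_idx],
        "pairs": {names[c]: names[s] for s, c, _ in spec.redundant_pairs},
        "noise": [
            names[j]
            for j in range(d)
            if j not in spec.informative_idx
            and j not in [c for _, c, _ in spec.redundant_pairs]
        ],
    }
    return pd.DataFrame(X, columns=names), labels.astype(int), truth
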