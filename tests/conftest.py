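"""Shared fixtures: tiny on-the-fly data files and reusable feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pmpso import (
    ExtractionConfig,
    SynthTableSpec,
    extract_feature_matrix,
    gen_eeg_dataset,
    gen_feature_table,
)
from pmpso.io import apply_filters, concat_segment_sets, segment_record


def write_minimal_edf(path, signals, fs, ch_names, phys_max=1000.0):
    """Write a minimal but standard-conforming EDF file (synthetic; for tests
    only).  One 1-second data record per fs samples, 16-bit little-endian."""
    n_ch = len(signals)
    spr = int(fs)
    n_rec = len(signals[0]) // spr

    def f(s, n):
        return str(s).ljust(n)[:n].encode("ascii")

    hdr = f("0", 8) + f("X X X X", 80) + f("Startdate 01-JAN-2020", 80)
    hdr += f("01.01.20", 8) + f("00.00.00", 8) + f(256 + n_ch * 256, 8) + f("", 44)
    hdr += f(n_rec, 8) + f(1.0, 8) + f(n_ch, 4)
    hdr += b"".join(f(n, 16) for n in ch_names)
    hdr += b"".join(f("", 80) for _ in range(n_ch))
    hdr += b"".join(f("uV", 8) for _ in range(n_ch))
    hdr += b"".join(f(-phys_max, 8) for _ in range(n_ch))
    hdr += b"".join(f(phys_max, 8) for _ in range(n_ch))
    hdr += b"".join(f(-32768, 8) for _ in range(n_ch))
    hdr += b"".join(f(32767, 8) for _ in range(n_ch))
    hdr += b"".join(f("", 80) for _ in range(n_ch))
    hdr += b"".join(f(spr, 8) for _ in range(n_ch))
    hdr += b"".join(f("", 32) for _ in range(n_ch))
    scale = 32767 / phys_max
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for ch in range(n_ch):
                seg = np.asarray(signals[ch][r * spr:(r + 1) * spr])
                dig = np.clip(np.round(seg * scale), -32768, 32767).astype("<i2")
                fh.write(dig.tobytes())


@pytest.fixture
def bonn_file(tmp_path):
    """A 4,097-line Bonn-dialect record file."""
    rng = np.random.default_rng(42)
    samples = rng.integers(-500, 500, size=4097)
    p = tmp_path / "Z001.txt"
    p.write_text("\n".join(str(v) for v in samples) + "\n")
    return p, samples


@pytest.fixture
def edf_file(tmp_path):
    fs = 256
    t = np.arange(fs * 4) / fs
    signals = [100 * np.sin(2 * np.pi * 10 * t), 50 * np.sin(2 * np.pi * 3 * t)]
    names = ["FP1-F7", "F7-T7"]
    p = tmp_path / "synthetic_chb.edf"
    write_minimal_edf(p, signals, fs, names)
    return p, signals, fs, names


@pytest.fixture(scope="session")
def toy_table():
    """8-feature table: 3 informative one-vs-rest columns + 5 noise."""
    spec = SynthTableSpec(
        n_samples=150, n_features=8, informative_idx=(0, 1, 2),
        effect_size=2.0, seed=3,
    )
    return gen_feature_table(spec)


@pytest.fixture(scope="session")
def dup_table():
    """12-feature table with exact duplicates of the informative columns."""
    spec = SynthTableSpec(
        n_samples=150, n_features=12, informative_idx=(0, 1, 2),
        effect_size=2.0,
        redundant_pairs=((0, 3, 1.0), (1, 4, 1.0), (2, 5, 1.0)),
        seed=7,
    )
    return gen_feature_table(spec)


@pytest.fixture(scope="session")
def eeg_features():
    """Feature matrix from a small filtered/segmented synthetic EEG dataset."""
    recs = [apply_filters(r) for r in gen_eeg_dataset(12, seed=11)]
    segs = concat_segment_sets([segment_record(r) for r in recs])
    return extract_feature_matrix(segs, ExtractionConfig())
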