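"""Shared fixtures: tiny montages, epoch builders, small synthetic datasets."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from feedcsp import ChannelMontage, EpochSet, SubjectMeta
from feedcsp import synthetic_data as sd


@pytest.fixture(scope="session")
def montage8() -> ChannelMontage:
    ang = 2 * np.pi * np.arange(8) / 8
    pos = np.c_[0.7 * np.cos(ang), 0.7 * np.sin(ang)]
    labels = ("FCz", "Cz", "Pz", "Oz", "F3", "F4", "P3", "P4")
    return ChannelMontage(labels=labels, positions=pos)


@pytest.fixture(scope="session")
def biosemi64() -> ChannelMontage:
    return ChannelMontage.standard_biosemi64()


def make_epochs(montage: ChannelMontage, n_pos: int = 6, n_neg: int = 6,
                n_samples: int = 870, srate: float = 256.0,
                t0: float = -1000.0, seed: int = 0,
                subject_id: str = "S000") -> EpochSet:
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    data = rng.standard_normal((n, len(montage), n_samples))
    valence = ("positive",) * n_pos + ("negative",) * n_neg
    return EpochSet(subject_id=subject_id, data=data, valence=valence,
                    srate=srate, t0=t0, montage=montage)


@pytest.fixture()
def epochs8(montage8) -> EpochSet:
    return make_epochs(montage8)


@pytest.fixture(scope="session")
def small_dataset():
    """20 subjects, 8 channels, planted frontal theta effect (fast)."""
    cfg = sd.recovery_config(n_per_group=10, n_channels=8,
                             trials_per_valence=8, seed=42)
    return sd.generate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def null_dataset16():
    """Zero-effect dataset: 16 channels, 12 subjects per class."""
    cfg = sd.null_config(n_per_group=12, n_channels=16,
                         trials_per_valence=8, seed=7)
    return sd.generate_dataset(cfg), cfg


def write_minimal_edf(path, data: np.ndarray, srate: float,
                      labels: list[str]) -> None:
    """Write a synthetic EDF file: one 1-s data record per epoch.

    Minimal standards-conforming writer used only to exercise the EDF import
    path on synthetic fixtures; ``data`` is trials x channels x samples with
    samples == srate (so each record spans exactly one second).
    """
    n_trials, n_ch, n_samp = data.shape
    assert n_samp == int(srate), "one-second records keep the header exact"
    phys_max = max(1.0, float(np.abs(data).max()) * 1.01)

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        assert len(b) <= width
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8), pad("", 44),
        pad(str(n_trials), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    fields = [
        ("".join([f"{lab:<16s}" for lab in labels]), 16),
        ("".join(["transducer".ljust(80) for _ in labels]), 80),
        ("".join(["uV".ljust(8) for _ in labels]), 8),
        ("".join([f"{-phys_max:<8.2f}"[:8] for _ in labels]), 8),
        ("".join([f"{phys_max:<8.2f}"[:8] for _ in labels]), 8),
        ("".join(["-32768".ljust(8) for _ in labels]), 8),
        ("".join(["32767".ljust(8) for _ in labels]), 8),
        ("".join(["".ljust(80) for _ in labels]), 80),
        ("".join([str(n_samp).ljust(8) for _ in labels]), 8),
        ("".join(["".ljust(32) for _ in labels]), 32),
    ]
    sig_header = b"".join(pad(text, width * n_ch) for text, width in fields)
    scale = 32767.0 / phys_max
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for trial in data:
            for ch in trial:
                ints = np.clip(np.round(ch * scale), -32768, 32767)
                fh.write(struct.pack(f"<{n_samp}h", *ints.astype(int)))
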