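"""Shared fixtures: tiny deterministic recordings and synthetic configs."""

from __future__ import annotations

import numpy as np
import pytest

from modrepair.signal_io import ModalityStream, Recording
from modrepair.synthetic import default_config, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_recording() -> Recording:
    """Two modalities at different rates, 20 s, deterministic content."""
    gen = np.random.default_rng(7)
    t64 = np.arange(20 * 64) / 64.0
    t32 = np.arange(20 * 32) / 32.0
    streams = {
        "imu": ModalityStream("imu", 64.0,
                              np.stack([np.sin(2 * np.pi * 1.3 * t64),
                                        np.cos(2 * np.pi * 0.7 * t64),
                                        gen.normal(size=t64.size)], axis=1)),
        "eda": ModalityStream("eda", 32.0,
                              (0.5 * np.sin(2 * np.pi * 0.1 * t32)
                               + 0.1 * gen.normal(size=t32.size))[:, None]),
    }
    labels = np.repeat([0, 1], 10 * 64)
    return Recording("T01", streams, labels, label_rate=64.0)


@pytest.fixture(scope="session")
def small_dataset():
    """Five-subject synthetic dataset at desk scale (10 Hz, 205 s)."""
    cfg = default_config(n_subjects=5, duration_s=205.0, rate=10.0, seed=42)
    return generate_dataset(cfg)
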