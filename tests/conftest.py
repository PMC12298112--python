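"""Shared fixtures: small synthetic recordings and on-disk export files.

Everything is generated at test time from seeds; no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

from tremorkit.recording import CHANNELS, RawRecording
from tremorkit.synth import SyntheticSpec, simulate_pair, write_pair


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_recording(
    n: int = 1000,
    fs: float = 100.0,
    convention: str = "canonical",
    seed: int = 0,
) -> RawRecording:
    """Plain white-noise recording for structural tests."""
    r = np.random.default_rng(seed)
    return RawRecording(
        device_id="test",
        timestamps=np.arange(n) / fs,
        channels={c: r.normal(size=n) for c in CHANNELS},
        nominal_fs=fs,
        axis_convention=convention,
    )


@pytest.fixture
def noise_recording() -> RawRecording:
    return make_recording()


@pytest.fixture
def clean_pair_spec() -> SyntheticSpec:
    """Noise-free, jitter-free acquisition with a modest tremor."""
    return SyntheticSpec(
        tremor_amp=0.5, noise_sd=0.0, fs_watch_mean=100.0,
        fs_watch_jitter_sd=0.0, delay=0.37, dup_row_rate=0.0, seed=3,
    )


@pytest.fixture
def realistic_pair_spec() -> SyntheticSpec:
    """Jittered, noisy, sign-flipped acquisition exercising every repair."""
    return SyntheticSpec(
        tremor_amp=0.6, noise_sd=0.2, delay=0.25,
        dup_row_rate=0.05, header_offset=4, seed=7,
    )


@pytest.fixture
def pair_files(tmp_path, realistic_pair_spec):
    """One simulated acquisition written as the two on-disk dialects."""
    pair = simulate_pair(realistic_pair_spec)
    paths = write_pair(pair, tmp_path, "fix", realistic_pair_spec)
    return paths, pair, realistic_pair_spec
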