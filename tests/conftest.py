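"""Shared fixtures: desk-scale synthetic studies, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from beatpipe.preprocess import preprocess_cortical, preprocess_ffr
from beatpipe.synth import SynthConfig, generate_study


@pytest.fixture(scope="session")
def mini_cfg() -> SynthConfig:
    """4 subjects, 16 channels, 64-s blocks at 1024 Hz (carriers representable)."""
    return SynthConfig(n_subjects=4, fs=1024.0, n_channels=16, block_s=64.0, seed=7)


@pytest.fixture(scope="session")
def mini_study(mini_cfg):
    recordings, vas = generate_study(mini_cfg)
    return recordings, vas


@pytest.fixture(scope="session")
def ffr_epochs(mini_study):
    recordings, _ = mini_study
    return {k: preprocess_ffr(rec) for k, rec in recordings.items()}


@pytest.fixture(scope="session")
def cortical_epochs(mini_study):
    recordings, _ = mini_study
    return {k: preprocess_cortical(rec) for k, rec in recordings.items()}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
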