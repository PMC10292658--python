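from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from blinkscore.synthetic import BlinkKinematicsParams, generate_trace
from blinkscore.types import CS_ONLY, PAIRED, US_ONSET_MS, TrialSpec


@pytest.fixture
def paired_spec() -> TrialSpec:
    return TrialSpec(PAIRED, cs_onset_ms=0.0, us_onset_ms=US_ONSET_MS)


@pytest.fixture
def cs_only_spec() -> TrialSpec:
    return TrialSpec(CS_ONLY, cs_onset_ms=0.0)


@pytest.fixture
def clean_params() -> BlinkKinematicsParams:
    """Noise-free kinematics with a deterministic CR at 150 ms."""
    return BlinkKinematicsParams(
        cr_probability=1.0,
        cr_onset_mean_ms=150.0,
        cr_onset_sd_ms=0.0,
        noise_sd_px=0.0,
        spontaneous_blink_rate_hz=0.0,
    )


@pytest.fixture
def noiseless_no_cr_params() -> BlinkKinematicsParams:
    return BlinkKinematicsParams(
        cr_probability=0.0, noise_sd_px=0.0, spontaneous_blink_rate_hz=0.0
    )


def make_trace(spec, params, seed=0, frame_rate=200.0):
    return generate_trace(spec, params, frame_rate, seed=seed)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
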