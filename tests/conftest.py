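"""Shared fixtures: all synthetic, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from neuroloop.deviation import make_synthetic_normative_db
from neuroloop.signal_gen import (
    GaussianPeak,
    Montage,
    SpectralModel,
    synthesize_recording,
)
from neuroloop.sourceloc import build_toy_headmodel


@pytest.fixture(scope="session")
def o1_montage() -> Montage:
    return Montage(channel_labels=("O1",), sampling_rate=256.0)


@pytest.fixture(scope="session")
def alpha_model() -> SpectralModel:
    """Aperiodic 1/f (x = 1.5) plus a clear 10 Hz alpha peak."""
    return SpectralModel(
        noise_floor=0.05, aperiodic_offset=10.0, aperiodic_exponent=1.5,
        peaks=(GaussianPeak(10.0, 2.0, 1.0),),
    )


@pytest.fixture(scope="session")
def alpha_recording(o1_montage, alpha_model):
    return synthesize_recording({"O1": alpha_model}, o1_montage, 120.0, seed=11)


@pytest.fixture(scope="session")
def toy_headmodel():
    return build_toy_headmodel(n_voxels=64, geometry="spherical")


@pytest.fixture(scope="session")
def normative_db():
    return make_synthetic_normative_db()
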