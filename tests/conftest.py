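"""Shared fixtures: models, small synthetic datasets, desk-scale budgets."""

import numpy as np
import pytest

from bmmi.inference import SMCSettings
from bmmi.models import build_model
from bmmi.synthetic_data import (
    SyntheticGroundTruth,
    generate_dose_response_data,
)


@pytest.fixture(scope="session")
def ma_model():
    return build_model("MA_CASCADE")


@pytest.fixture(scope="session")
def fb_model():
    return build_model("FB_CASCADE")


@pytest.fixture(scope="session")
def rap1_model():
    return build_model("RAP1_CASCADE")


@pytest.fixture(scope="session")
def doses_10():
    return np.logspace(np.log10(0.001), np.log10(0.106), 10)


@pytest.fixture(scope="session")
def dose_response_data(ma_model):
    """The 10-point noisy dose-response dataset (noise sd 0.1)."""
    truth = SyntheticGroundTruth(
        "MA_CASCADE", ma_model.params_nominal, noise_sd=0.1, seed=11
    )
    return generate_dose_response_data(truth)


@pytest.fixture(scope="session")
def small_smc():
    """Desk-scale sampler budget for ODE-model fits in tests."""
    return SMCSettings(n_chains=2, s_per_chain=150, max_mh_steps=4, seed=0)


@pytest.fixture(scope="session")
def tiny_smc():
    """Minimal budget for replicate studies."""
    return SMCSettings(n_chains=1, s_per_chain=120, max_mh_steps=4, seed=0)
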