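import numpy as np
import pytest

from hypohop.model_core import build_default_model
from hypohop.mtu_geometry import fit_model_geometry
from hypohop.preprocessing import preprocess_trial
from hypohop.synth_data import SynthConfig, generate_condition_trial


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def geometry(model):
    return fit_model_geometry(model)


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(seed=0)


@pytest.fixture(scope="session")
def clean_trial(model, synth_config):
    """Noise-free synthetic trial at Mars-like gravity."""
    return generate_condition_trial(model, synth_config, 0.37, noise=False)


@pytest.fixture(scope="session")
def clean_tracking_data(model, clean_trial):
    return preprocess_trial(clean_trial, model)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
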