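import numpy as np
import pytest

from lyoscat import synth


@pytest.fixture(scope="session")
def preset_models():
    return {name: synth.preset_model(name) for name in synth.preset_names()}


@pytest.fixture(scope="session")
def unloaded_curve():
    """Noiseless curve from the unloaded preset on the instrument grid."""
    return synth.synth_preset_curve("unloaded", noise_level=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
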