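import numpy as np
import pytest

from gaitphase.gait_synth import SynthConfig, synth_features, synth_walk


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial: walk, 180° turn with small steps, walk back."""
    return synth_walk(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def default_features():
    """Cleaned, featurized default trial (both legs) plus ground truth."""
    features, truth, turning = synth_features(SynthConfig(seed=42))
    return features, truth, turning


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
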