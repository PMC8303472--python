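import numpy as np
import pytest

from echocalc.phantom import default_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noisy_scene():
    return default_scene(seed=7)


@pytest.fixture
def noiseless_scene():
    return default_scene(seed=7, speckle_sigma=0.0)
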