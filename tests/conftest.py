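import numpy as np
import pytest

from emocert.synthgen import SynthConfig, gen_atlas


@pytest.fixture(scope="session")
def cfg():
    return SynthConfig(seed=2024)


@pytest.fixture(scope="session")
def atlas(cfg):
    return gen_atlas(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
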