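import numpy as np
import pytest
from hypothesis import settings

from dbsbias.synthesize import DEFAULT_MODELS, DonorSet, NoiseSpec

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def models():
    return DEFAULT_MODELS


@pytest.fixture()
def donors():
    return DonorSet(n_donors=5, hct_levels=(0.2, 0.3, 0.4, 0.5, 0.6), seed=0)


@pytest.fixture()
def no_noise():
    return NoiseSpec(accuracy_pct=100.0, rsd_pct=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
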