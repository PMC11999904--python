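import numpy as np
import pytest

from headms import phantom


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small in-memory cohort (64x64, 12 subjects) shared by fast tests."""
    params = phantom.PhantomParams(image_size=64)
    return phantom.generate_cohort(12, params, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
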