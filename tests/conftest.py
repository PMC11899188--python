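import numpy as np
import pytest

from spectroheal.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (short decays) shared by read-only tests."""
    cfg = CohortConfig(n_echoes=500, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
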