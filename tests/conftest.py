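import numpy as np
import pytest

from afgrs import SimConfig, load_panel, simulate_cohort


@pytest.fixture(scope="session")
def panel12():
    return load_panel("af12")


@pytest.fixture(scope="session")
def panel9():
    return load_panel("af9")


@pytest.fixture(scope="session")
def cohort904(panel12):
    """A study-sized synthetic cohort under the default quintile-rate outcome."""
    return simulate_cohort(SimConfig(n_participants=904, panel=panel12, seed=20130))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
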