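import numpy as np
import pytest

from cyclephys import cohort as syn


@pytest.fixture(scope="session")
def small_cohort():
    """Six riders with latent physiology, fixed seed."""
    return syn.generate_cohort(6, 11)


@pytest.fixture(scope="session")
def rider(small_cohort):
    """One representative (participant, physiology) pair."""
    return small_cohort[2]


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
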