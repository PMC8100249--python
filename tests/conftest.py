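import numpy as np
import pytest

from locomode import CohortConfig, FeatureStore, WindowSpec, default_channel_set, generate_cohort


@pytest.fixture(scope="session")
def small_channels():
    """A reduced channel set for fast unit tests."""
    return default_channel_set()[:8]


@pytest.fixture(scope="session")
def small_config(small_channels):
    return CohortConfig(
        n_subjects=2, trials_per_condition=3, channel_set=list(small_channels), seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_store(small_cohort):
    return FeatureStore(small_cohort, WindowSpec(300.0, 25.0))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
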