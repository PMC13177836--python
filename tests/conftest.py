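import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from divmeta import diversity_uncertainty_preset, effects_from_records, generate_dataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """A small preset dataset shared by read-only tests."""
    return generate_dataset(diversity_uncertainty_preset(seed=42, n_studies=12))


@pytest.fixture(scope="session")
def small_smd_effects(small_dataset):
    return effects_from_records(small_dataset.comparisons, "SMD")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
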