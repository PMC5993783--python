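import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from morphoscore.simulate import FeatureSchema, simulate_case_control

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_schema():
    """Tiny morphometry layout (64 features) for fast model tests."""
    return FeatureSchema(n_vertices=10, n_subcortical=4)


@pytest.fixture(scope="session")
def small_training_set(small_schema):
    """Well-separated case/control training data on the tiny schema."""
    return simulate_case_control(12, 10, 3.0, schema=small_schema, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
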