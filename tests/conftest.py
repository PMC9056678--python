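import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """Small synthetic formula/value table shared across model tests."""
    from econfqspr.synth import SyntheticSpec, generate_table

    table, beta = generate_table(SyntheticSpec(n_compounds=80, seed=3))
    return table, beta


@pytest.fixture(scope="session")
def small_featurized(small_table):
    from econfqspr.data import split_dataset
    from econfqspr.models import FeaturizedSplit

    table, _ = small_table
    split = split_dataset(table, ratio=0.2, seed=1)
    return FeaturizedSplit.from_split(split)
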