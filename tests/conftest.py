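import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from aprnet import AggregationNet, default_feature_table
from aprnet.synthetic import SyntheticSpec, gen_annotated_proteins, gen_hexapeptides

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def feature_table():
    return default_feature_table()


@pytest.fixture(scope="session")
def hex_dataset():
    """Noise-free separable hexapeptide dataset."""
    return gen_hexapeptides(SyntheticSpec(n_hexapeptides=200, positive_fraction=0.4,
                                          noise=0.0, seed=11))


@pytest.fixture(scope="session")
def annotated_proteins():
    return gen_annotated_proteins(4, length_range=(60, 100), seed=21)


@pytest.fixture(scope="session")
def fitted(hex_dataset, feature_table):
    """A quickly fitted ensemble shared across tests that need one."""
    model = AggregationNet(hex_dataset, feature_table=feature_table)
    return model.fit(seed=11, max_epochs=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
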