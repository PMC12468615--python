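import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eegentropy.features import FeatureConfig, extract_batch
from eegentropy.synthetic import SyntheticConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: master seed of the default study dataset used across the suite
DATASET_SEED = 20250901


@pytest.fixture(scope="session")
def two_class_dataset():
    """The default two-class synthetic dataset: 100 background +
    100 ictal-like segments of 4097 samples at 173.61 Hz."""
    return generate_dataset(SyntheticConfig.two_class(seed=DATASET_SEED))


@pytest.fixture(scope="session")
def two_class_features(two_class_dataset):
    """Full MDE feature batch of the default dataset (extracted once)."""
    batch = extract_batch(two_class_dataset.signals, FeatureConfig())
    batch.labels = two_class_dataset.labels
    return batch


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
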