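import numpy as np
import pytest

from artflow.flow import CameraModel, DatasetSpec, generate_dataset
from artflow.mt import encode_sequences
from artflow.network import sample_partitioned_population


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cloud(camera):
    """Small translation-only cloud dataset shared across test modules."""
    spec = DatasetSpec(environment="cloud_T", n_train=24, n_test=10, seed=42)
    train, test = generate_dataset(spec, camera)
    return spec, train, test


@pytest.fixture(scope="session")
def small_encoded(camera, tiny_cloud):
    """MT-encoded tiny cloud dataset with a small partitioned population."""
    _, train, test = tiny_cloud
    pop, part = sample_partitioned_population(1200, camera, (8, 8), seed=7)
    return {
        "population": pop,
        "partition": part,
        "train": encode_sequences(train, pop),
        "test": encode_sequences(test, pop),
        "train_seqs": train,
        "test_seqs": test,
    }
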