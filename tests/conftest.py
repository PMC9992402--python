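import numpy as np
import pytest

from epitopenet.model import ModelConfig
from epitopenet.seqio import encode_batch
from epitopenet.synth import SynthSpec, generate


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """A structurally complete but very small model for fast protocol tests."""
    return ModelConfig(
        embed_dim=8,
        lstm_units=8,
        cnn_filters=8,
        dense_sizes=(8, 3, 1),
        dropout_rate=0.1,
        seed=7,
        epochs=2,
        batch_size=16,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """60 balanced synthetic records with a fully penetrant motif."""
    return generate(SynthSpec(n_pos=30, n_neg=30, seed=11))


@pytest.fixture(scope="session")
def small_batch(small_dataset):
    return encode_batch(small_dataset, 25)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
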