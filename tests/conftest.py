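import numpy as np
import pytest

from deepcytometry import network, prep, simulate


@pytest.fixture(scope="session")
def scaled_config():
    """Down-scaled instrument preset used for fast end-to-end runs."""
    return simulate.SimConfig.scaled()


@pytest.fixture(scope="session")
def small_cohort(scaled_config):
    """Six waveforms (~600 elements) for pipeline tests."""
    waveforms, manifest = simulate.generate_cohort(scaled_config, 6, seed=7)
    return waveforms, manifest


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    waveforms, _ = small_cohort
    X, y, manifest = prep.prepare_dataset(waveforms, reduction_factor=4)
    return X, y, manifest


@pytest.fixture
def tiny_model_config(small_dataset):
    """A minimal architecture over the scaled element shape."""
    X, _, _ = small_dataset
    return network.ModelConfig(
        conv_blocks=((1, 4), (1, 4), (1, 8)), fc_sizes=(16, 3),
        dropout_keep_prob=1.0, l2_multiplier=0.0,
        input_shape=X.shape[1:])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
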