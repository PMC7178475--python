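import numpy as np
import pytest

from nsstfuse import phantoms, weightnet
from nsstfuse.nsst import build_filter_bank


@pytest.fixture(scope="session")
def small_bank():
    """Modest bank for 64x64 unit tests (2 levels keeps the support small)."""
    return build_filter_bank(2, [4, 8], (64, 64))


@pytest.fixture(scope="session")
def default_bank_256():
    return build_filter_bank(4, [8, 8, 16, 16], (256, 256))


@pytest.fixture(scope="session")
def train_corpus():
    return phantoms.make_blur_corpus(n_images=12, seed=7)


@pytest.fixture(scope="session")
def trained_params(train_corpus):
    """A compact trained model shared by pipeline-level tests.

    1500 pairs / 5 epochs is enough to saturate the sharp/blur task; the
    full-size training run has its own dedicated test.
    """
    dataset = weightnet.make_patch_dataset(
        [sharp for sharp, _, _ in train_corpus], blur_sigma=(1.0, 3.0),
        patch_size=16, n_pairs=1500, seed=7)
    return weightnet.train_network(dataset, epochs=5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
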