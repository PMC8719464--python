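import numpy as np
import pytest

from perceptcad.extractor import ExtractorConfig
from perceptcad.phantom import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cases():
    """40 phantom cases at the 64-px test scale (shared, read-only)."""
    cases, manifest = generate_dataset(PhantomConfig(n_cases=40, seed=123))
    return cases, manifest


@pytest.fixture(scope="session")
def tiny_extractor_config():
    """A minutes-scale network profile for unit tests (32 px, 1/16 width)."""
    return ExtractorConfig(
        input_side=32,
        width_multiplier=1 / 16,
        fc_sizes=(64, 64, 128),
        dropout_rate=0.0,
        lr_init=1e-3,
        lr_decay_epochs=(8,),
        max_epochs=10,
        batch_size=4,
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
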