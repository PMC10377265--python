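import numpy as np
import pytest

from mammober.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but learnable synthetic set shared across tests."""
    cfg = SyntheticConfig(n_per_class=20, image_size=32, seed=42)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
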