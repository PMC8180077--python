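import numpy as np
import pytest

from placim.phantom import PhantomSpec, generate_records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small noise-free phantom world shared across tests."""
    return PhantomSpec(image_size=64, n_per_class=3, noise_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def tiny_records(tiny_spec):
    return generate_records(tiny_spec)
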