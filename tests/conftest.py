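import numpy as np
import pytest

from sctdir.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_128():
    """Default 128x128 phantom + structures, shared across tests."""
    return generate_phantom(PhantomConfig(seed=3))


@pytest.fixture(scope="session")
def phantom_64():
    return generate_phantom(PhantomConfig(shape=(64, 64), seed=3))


@pytest.fixture
def float64_tensors():
    """Run the autodiff engine in float64 for finite-difference checks."""
    from sctdir.nn import tensor

    old = tensor.DTYPE
    tensor.set_default_dtype(np.float64)
    yield
    tensor.DTYPE = old
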