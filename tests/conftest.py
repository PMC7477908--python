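import numpy as np
import pytest

from asdlmri import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom128():
    return generate_phantom(PhantomSpec(grid_size=128))


@pytest.fixture(scope="session")
def phantom64():
    return generate_phantom(PhantomSpec(grid_size=64))


def unit_norm_dictionary(rng, m, n, complex_valued=False):
    D = rng.standard_normal((m, n))
    if complex_valued:
        D = D + 1j * rng.standard_normal((m, n))
    return D / np.linalg.norm(D, axis=0, keepdims=True)
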