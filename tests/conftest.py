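import numpy as np
import pytest

from lvseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230101)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 128-px phantom shared across tests."""
    return generate_phantom(PhantomConfig(image_size=128, seed=7))


def numeric_gradient(f, x, eps=1e-6):
    """Central-difference gradient of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g
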