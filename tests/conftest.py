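import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_kernel_set():
    """Shared 6-class synthetic fixture at 32x32 (fast)."""
    from grainforge.image_data import make_synthetic_kernel_set
    return make_synthetic_kernel_set(10, seed=0, image_size=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def fd_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at x (dense, for tiny arrays)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
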