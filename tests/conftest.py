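import numpy as np
import pytest
from hypothesis import settings

from gmchaos.volume_io import GMVolume

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iso_affine():
    """1.5 mm isotropic affine, the resolution of normalized GM maps."""
    return np.diag([1.5, 1.5, 1.5, 1.0])


@pytest.fixture
def random_volume(rng, iso_affine):
    data = rng.random((6, 6, 6))
    return GMVolume(data=data, affine=iso_affine, subject_id="rand6")


def logistic_series(n: int, x0: float = 0.37) -> np.ndarray:
    """Fully chaotic logistic map orbit, x_{i+1} = 4 x_i (1 - x_i)."""
    x = np.empty(n)
    x[0] = x0
    for i in range(n - 1):
        x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
    return x
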