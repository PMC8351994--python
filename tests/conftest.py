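import numpy as np
import pytest

from nichepack.ecology import Community, ecological_equilibrium
from nichepack.kernels import ModelParams


@pytest.fixture
def quartic():
    return ModelParams(carrying_kind="quartic", sigma_alpha=0.5)


@pytest.fixture
def radial():
    return ModelParams(carrying_kind="radial", sigma_alpha=0.5)


@pytest.fixture
def asymmetric():
    return ModelParams(
        carrying_kind="quartic",
        sigma_alpha=0.5,
        b=np.array([[0.0, 1.0], [-1.0, 0.0]]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_community(rng, m, spread=1.2, params=None, equilibrate=False, min_spacing=0.0):
    """Random community helper; optionally at its ecological equilibrium.

    ``min_spacing`` rejects draws with near-duplicate phenotypes (the merge
    step removes those before any equilibrium computation in real runs).
    """
    while True:
        z = rng.uniform(-spread, spread, size=(m, 2))
        if min_spacing <= 0:
            break
        diff = z[:, None, :] - z[None, :, :]
        dist = np.linalg.norm(diff, axis=-1) + np.eye(m) * 1e9
        if dist.min() >= min_spacing:
            break
    c = Community(z, rng.uniform(0.05, 0.5, size=m))
    if equilibrate:
        assert params is not None
        return ecological_equilibrium(c, params)
    return c
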