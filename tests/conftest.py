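import numpy as np
import pytest

from refmix.mixture import MixtureParameterSurface


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_surface(rng, n=20, m=2):
    """A valid random parameter surface for property checks."""
    raw = rng.uniform(0.2, 1.0, size=(n, m))
    weights = raw / raw.sum(axis=1, keepdims=True)
    means = rng.normal(0.0, 2.0, size=(n, m))
    scales = rng.uniform(0.3, 2.0, size=(n, m))
    return MixtureParameterSurface(weights, means, scales)


@pytest.fixture
def surface_factory(rng):
    return lambda n=20, m=2: random_surface(rng, n, m)
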