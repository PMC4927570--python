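import numpy as np
import pytest

from cbfcovnet import modular_model, sample_cohort


@pytest.fixture(scope="session")
def small_model():
    """30 regions in 3 modules: fast but structurally nontrivial."""
    return modular_model(n_regions=30, n_modules=3)


@pytest.fixture(scope="session")
def small_cohort(small_model):
    return sample_cohort(small_model, 40, seed=11, group="control")


@pytest.fixture(scope="session")
def default_model():
    """The reference configuration: 90 regions in 6 modules of 15."""
    return modular_model()


def random_adjacency(rng, n=10, density=0.4, weighted=True):
    """Random symmetric nonnegative adjacency with zero diagonal."""
    w = rng.random((n, n))
    keep = rng.random((n, n)) < density
    w = np.where(keep, 0.2 + 0.8 * w, 0.0)
    w = np.triu(w, 1)
    w = w + w.T
    if not weighted:
        w = (w > 0).astype(float)
    return w
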