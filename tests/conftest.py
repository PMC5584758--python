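import numpy as np
import pytest

from reefscape.synthetic_data import StudyConfig, gen_study
from reefscape.trace_processing import TransectProfile


@pytest.fixture
def flat_profile():
    x = np.arange(0.0, 30.01, 0.1)
    return TransectProfile(distance=x, depth=np.full_like(x, 20.0),
                           transect_length=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_profile(rng, n_max=60, n_min=5):
    """Small random profile for oracle comparisons."""
    n = int(rng.integers(n_min, n_max + 1))
    length = float(n - 1) * 0.1
    x = np.linspace(0.0, length, n)
    depth = 20.0 + rng.normal(0, 1.0, size=n).cumsum() * 0.1
    return TransectProfile(distance=x, depth=depth, transect_length=length)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study with traces (shared across tests)."""
    config = StudyConfig(n_natural_sites=4, n_artificial_sites=4,
                         seasons=("summer",), seed=7)
    return gen_study(config)


@pytest.fixture(scope="session")
def glm_study():
    """A larger traceless study for model-fitting tests."""
    config = StudyConfig(n_natural_sites=10, n_artificial_sites=10,
                         seasons=("summer", "fall"), generate_traces=False,
                         seed=13)
    return gen_study(config)
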