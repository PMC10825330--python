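import numpy as np
import pytest

from uaextract import fixtures
from uaextract.synth import default_study, generate_surface_study


@pytest.fixture(scope="session")
def factors():
    return fixtures.load_factors()


@pytest.fixture(scope="session")
def study():
    """Default synthetic study, seed 42."""
    return default_study(seed=42)


@pytest.fixture(scope="session")
def noisy_design(study):
    return generate_surface_study(study)


@pytest.fixture(scope="session")
def noiseless_design():
    spec = default_study(seed=1, noise_frac=0.0)
    return generate_surface_study(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
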