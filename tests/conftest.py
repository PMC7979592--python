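import numpy as np
import pytest
from hypothesis import settings

from mqsofa.synthetic import GeneratorParams, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """One exact-mode cohort at the packaged joint distribution (n = 1001)."""
    return generate_cohort(GeneratorParams(seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """Exact-mode cohort at 20x scale (n = 20020) for convergence checks."""
    return generate_cohort(GeneratorParams(seed=7, scale=20))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
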