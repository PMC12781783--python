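import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from mclrp import GeneratorSpec, generate, normalize_response
from mclrp.pca import fit_pca


@pytest.fixture(scope="session")
def small_bundle():
    """Noiseless responses exactly in the expression score span."""
    return generate(GeneratorSpec(m=60, n=150, p=8, k_true=3, noise_sd=0.0,
                                  missing_fraction=0.2, span_leak=0.0,
                                  seed=7))


@pytest.fixture(scope="session")
def noisy_bundle():
    return generate(GeneratorSpec(m=80, n=200, p=12, k_true=4, noise_sd=0.1,
                                  missing_fraction=0.3, span_leak=0.1,
                                  mutation_effects=[(3, 1, 3.0)], seed=11))


@pytest.fixture(scope="session")
def normalized_small(small_bundle):
    return normalize_response(small_bundle.response)


@pytest.fixture(scope="session")
def small_pca(small_bundle):
    return fit_pca(small_bundle.expression)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
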