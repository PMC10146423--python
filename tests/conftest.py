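import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# scipy's trust-constr warns about singular constraint Jacobians on
# degenerate (but valid) active sets; the independent row checker guards
# correctness.
warnings.filterwarnings(
    "ignore", message="Singular Jacobian matrix", category=UserWarning)


@pytest.fixture(scope="session")
def fixture_system():
    from thriftyqp import toy_fixture
    return toy_fixture()


@pytest.fixture(scope="session")
def small_system():
    """Small but full-scheme synthetic system shared across tests."""
    from thriftyqp import generate_system
    return generate_system(seed=3, n_items=800, n_per_group=250)
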