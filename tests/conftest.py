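import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_model():
    """The packaged, calibrated baseline model (built once per session)."""
    from kneeflex.personalization import build_baseline_model
    return build_baseline_model()


@pytest.fixture(scope="session")
def experimental_stats():
    from kneeflex.pipeline import load_experimental_stats
    return load_experimental_stats()


@pytest.fixture(scope="session")
def baseline_result(baseline_model):
    from kneeflex.scenarios import baseline_moments
    return baseline_moments(baseline_model)
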