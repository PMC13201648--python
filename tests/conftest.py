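import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, shared across tests (read-only)."""
    from lumishift import simulate_cohort

    return simulate_cohort()


@pytest.fixture(scope="session")
def chromatin_data():
    """Default synthetic chromatin landscape, shared across tests."""
    from lumishift import simulate_peaks_and_motifs

    return simulate_peaks_and_motifs()
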