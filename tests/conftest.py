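import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from satmut import GeneratorConfig, ProteinSet, simulate_study  # noqa: E402


@pytest.fixture
def tiny_proteome() -> ProteinSet:
    return ProteinSet.from_sequences([("P1", "ACDE"), ("P2", "WYCK")])


@pytest.fixture(scope="session")
def small_study():
    """A mid-sized synthetic study shared by read-only tests."""
    return simulate_study(GeneratorConfig(n_proteins=6, length_range=(130, 170), seed=7))
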