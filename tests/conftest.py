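import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "crcdss",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("crcdss")

from crcdss import Registry, SimulationConfig, generate_registry  # noqa: E402


@pytest.fixture(scope="session")
def small_cohort():
    """120 synthetic patients with planted truth (seed fixed for the session)."""
    records, truth = generate_registry(SimulationConfig(seed=7, n_patients=120))
    return records, truth


@pytest.fixture(scope="session")
def loaded_registry(small_cohort):
    records, _ = small_cohort
    reg = Registry(k=5)
    reg.bulk_load(records)
    return reg
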