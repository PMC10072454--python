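import pytest

from ssbtax import CohortSpec, calibrate_market, generate_adult_cohort

#: Published Table-3-style per-capita energy decreases, kJ/person/day.
ENERGY_DELTAS = {
    "scenario1": 13.7,
    "scenario2": 26.2,
    "scenario3": 54.0,
    "scenario4": 52.4,
    "scenario5": 54.9,
}


@pytest.fixture(scope="session")
def calibration():
    """Aggregate market calibrated from the scenario-1 outcome."""
    return calibrate_market(energy_decrease_s1=13.7)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort for fast downstream tests."""
    return generate_adult_cohort(CohortSpec(n=5000, seed=7))


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort for calibration-recovery checks (sampling noise small)."""
    return generate_adult_cohort(CohortSpec(n=50_000, seed=123))
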