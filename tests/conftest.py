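import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic cohort shared by unit tests (12,000 visits)."""
    from htndtr.synthetic_cohort import SimulationConfig, simulate_dataset

    return simulate_dataset(
        SimulationConfig(n_patients=2000, horizon=6, seed=11)
    )


@pytest.fixture(scope="session")
def small_visits(small_dataset):
    from htndtr import cohort_builder as cb

    ids = cb.select_cohort(
        small_dataset.claims,
        small_dataset.prescriptions,
        small_dataset.checkups,
    )
    return cb.build_visit_states(
        small_dataset.checkups,
        small_dataset.claims,
        small_dataset.prescriptions,
        ids,
    )
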