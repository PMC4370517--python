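import numpy as np
import pytest
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
def small_design():
    """A coarse, fast two-masker design used by several end-to-end tests."""
    from cimasking import virtual_listener as vl

    return vl.ExperimentDesign(
        probe_places=tuple(np.round(np.arange(1.0, 13.01, 0.5), 4)),
        seed=11,
    )


@pytest.fixture(scope="session")
def cohort_table(small_design):
    """One stochastic 6-subject dataset, shared across read-only tests."""
    from cimasking import virtual_listener as vl

    cohort = vl.default_cohort_params(6, seed=11)
    return vl.generate_experiment_dataset(cohort, small_design)
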