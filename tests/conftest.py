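import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 5000.0
DURATION = 21.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def quiet_params():
    """Default condition parameters with every noise source disabled."""
    from ergflick.synthetic_data import DEFAULT_CONDITION_PARAMS

    return {c: p.quiet() for c, p in DEFAULT_CONDITION_PARAMS.items()}


@pytest.fixture(scope="session")
def exp1_cohort_measures():
    """Default-noise exp-1 cohort (8 crabs x 4 conditions) measured through
    the full preprocessing + spectral pipeline.  Session-scoped: several
    tests share this, the costliest fixture in the suite."""
    import ergflick as ef

    cohort = ef.CohortConfig()
    ds = ef.simulate_cohort_exp1(cohort, seed=42)
    measures = ef.measure_dataset(ds)
    return ds, measures
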