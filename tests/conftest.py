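import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_result():
    """One full desk-scale study (shared across acceptance tests)."""
    from grndiff.pipeline import run_desk_study

    return run_desk_study(seed=1)


@pytest.fixture(scope="session")
def null_calibration_98():
    """Null calibration at the paired-cohort sample size."""
    from grndiff.mi import calibrate_null

    return calibrate_null(98, n_permutations=10_000, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
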