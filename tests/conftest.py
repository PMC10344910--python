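import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # oracle helper modules

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_physiological_eyes(n: int, seed: int) -> np.ndarray:
    """(n, 3) array of (axl, cr, a_constant) spanning the physiological
    envelope the study describes, including long and short eyes."""
    rng = np.random.default_rng(seed)
    axl = rng.uniform(20.5, 30.5, n)
    cr = rng.uniform(6.72, 8.54, n)
    a = rng.uniform(118.0, 120.0, n)
    return np.column_stack([axl, cr, a])


@pytest.fixture(scope="session")
def small_cohort():
    from iolsvr import cohort

    return cohort.generate_cohort(cohort.CohortParams(n=300, seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """mrse identically equal to the SRK/T prediction (no bias, no noise)."""
    from iolsvr import cohort

    return cohort.generate_cohort(
        cohort.CohortParams(n=300, seed=11), bias=cohort.ZERO_BIAS
    )
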