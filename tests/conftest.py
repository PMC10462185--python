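import io

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from homtest import GrowthSimParams, TimepointPairData, generate_growth_study, read_long_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL_CSV = """animal_id,group,time,volume
m1,A,3,4.1
m1,A,5,9.0
m2,A,3,3.9
m2,A,5,8.5
m3,A,3,4.3
m3,A,5,9.4
m4,B,3,4.0
m4,B,5,7.2
m5,B,3,4.2
m5,B,5,7.9
m6,B,3,3.8
m6,B,5,7.0
"""


@pytest.fixture
def small_csv():
    return io.StringIO(SMALL_CSV)


@pytest.fixture
def small_study():
    return read_long_table(io.StringIO(SMALL_CSV))


@pytest.fixture
def growth_study():
    """Deterministic 2x10 animal study over the default 9-day grid."""
    return generate_growth_study(GrowthSimParams(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_pair(rng, n0=6, n1=6, effect=0.0, rho_slope=1.0, sigma=0.5):
    """Arbitrary well-conditioned pair data for identity checks."""
    yp0 = rng.normal(size=n0)
    yp1 = rng.normal(size=n1)
    yc0 = rho_slope * yp0 + sigma * rng.normal(size=n0)
    yc1 = effect + rho_slope * yp1 + sigma * rng.normal(size=n1)
    return TimepointPairData(0.0, 1.0, yp0, yc0, yp1, yc1)
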