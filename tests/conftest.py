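import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from bdscnn import generate_record
from bdscnn.preprocess import segment_beats

TABLE3 = np.array([
    [12718, 98, 57, 20, 57],
    [134, 469, 3, 0, 2],
    [102, 15, 1410, 12, 18],
    [29, 1, 6, 125, 0],
    [18, 0, 2, 0, 1619],
])


@pytest.fixture(scope="session")
def table3():
    return TABLE3.copy()


@pytest.fixture(scope="session")
def small_record():
    return generate_record(60, [0.4, 0.15, 0.15, 0.15, 0.15], rng_seed=11)


@pytest.fixture(scope="session")
def small_beats(small_record):
    return segment_beats(small_record)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
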