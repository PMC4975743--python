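import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def op_matrix(op, shape):
    """Dense matrix of a linear image->image map by probing basis vectors."""
    n = shape[0] * shape[1]
    M = np.zeros((n, n))
    e = np.zeros(n)
    for j in range(n):
        e[:] = 0.0
        e[j] = 1.0
        M[:, j] = np.asarray(op(e.reshape(shape))).ravel()
    return M


@pytest.fixture(scope="session")
def fixture_suite_64():
    """The three 64x64 (clean, psf, degraded) fixture triples, fixed seed."""
    from tgvdeblur.synthetic import make_fixture_suite

    return make_fixture_suite(seed=0, sizes=(64,))
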