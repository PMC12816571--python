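import numpy as np
import pytest

from cimkit import CIMSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_schedule():
    return CIMSchedule.default()


@pytest.fixture(scope="session")
def fast_schedule():
    """Short schedule for unit tests on tiny problems."""
    return CIMSchedule.default(rounds=200)


def random_ising(rng, n, field_scale=0.0):
    """Dense random Ising instance for oracle comparisons."""
    J = rng.normal(size=(n, n))
    J = (J + J.T) / 2
    np.fill_diagonal(J, 0.0)
    h = rng.normal(scale=field_scale, size=n) if field_scale else None
    from cimkit import IsingProblem

    return IsingProblem(J=J, h=h, offset=float(rng.normal()))


def random_qubo(rng, n):
    from cimkit import QUBOProblem

    Q = np.triu(rng.normal(size=(n, n)))
    return QUBOProblem(Q=Q, offset=float(rng.normal()))
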