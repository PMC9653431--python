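import numpy as np
import pytest

from phipsot import builtin_system
from phipsot.esotheric import SequenceRunner


@pytest.fixture(scope="session")
def ep3():
    return builtin_system("ep_d6_3spin")


@pytest.fixture(scope="session")
def abx():
    return builtin_system("fig2_abx")


@pytest.fixture(scope="session")
def ab2x():
    return builtin_system("fig2_ab2x")


@pytest.fixture(scope="session")
def abdx():
    return builtin_system("fig2_abdx")


@pytest.fixture()
def runner(ep3):
    return SequenceRunner(ep3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220901)
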