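import numpy as np
import pytest

from morankernels import core, public_goods, repeated_pd


@pytest.fixture(scope="session")
def pd_spec():
    return repeated_pd.default_repeated_game()


@pytest.fixture(scope="session")
def pd_game(pd_spec):
    return repeated_pd.payoff_matrix_8(pd_spec)


@pytest.fixture(scope="session")
def pgg_params():
    return public_goods.default_pgg_params()


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


def random_2x2(rng, low=0.0, high=10.0, labels=("A", "B")):
    return core.PayoffMatrix(values=rng.uniform(low, high, size=(2, 2)), labels=labels)
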