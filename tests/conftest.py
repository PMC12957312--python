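import numpy as np
import pytest

from popgeom.simulate import SimConfig, make_session


@pytest.fixture(scope="session")
def small_cfg():
    # compact session: fast enough for unit tests, rich enough to carry
    # all four task roles
    return SimConfig(n_units=40, trials_per_condition=15, n_bins=60, seed=11)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    session, _ = make_session(small_cfg)
    return session


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    _, truth = make_session(small_cfg)
    return truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
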