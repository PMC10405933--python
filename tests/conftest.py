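import numpy as np
import pytest

from envirogs import simulate_trial


@pytest.fixture(scope="session")
def tiny_trial():
    """Small balanced trial with signal: 4 environments x 12 lines."""
    trial, truth = simulate_trial(
        J=12, I=4, p=30, r=8, n_informative=2, mu=10.0, seed=7
    )
    return trial, truth


@pytest.fixture(scope="session")
def usp_shaped_trial():
    """A trial shaped like a 4-environment, 100-line hybrid panel."""
    trial, truth = simulate_trial(J=100, I=4, p=120, r=12, n_informative=3, mu=10.0, seed=11)
    return trial, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
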