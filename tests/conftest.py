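import numpy as np
import pytest

from beltcover import DepositionParams, PlateSpec, run_experiment


@pytest.fixture(scope="session")
def plate():
    return PlateSpec()


@pytest.fixture(scope="session")
def week12_run():
    """One 48-h week-12 deposition experiment (seed 0), shared across tests."""
    params = DepositionParams(seed=0)
    truth, state = run_experiment(params, daylength_h=13, duration_h=48)
    return params, truth, state


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
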