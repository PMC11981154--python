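import numpy as np
import pytest

import sacsim as s

#: single fixed seed stream for every stochastic ensemble in the suite
SUITE_SEED = 2025


@pytest.fixture(scope="session")
def params():
    return s.ModelParameters.molecules()


@pytest.fixture(scope="session")
def params_nm():
    return s.ModelParameters.nanomolar()


@pytest.fixture(scope="session")
def on_state():
    return s.checkpoint_on_state()


@pytest.fixture(scope="session")
def wt_washout(params):
    """Shared wild-type washout ensemble (n=60)."""
    proto = s.ProtocolSpec(mode="washout", nUK0=10)
    return s.run_ensemble(proto, params, n=60, seed0=SUITE_SEED)


@pytest.fixture(scope="session")
def wt_arrest(params):
    """Shared wild-type fixed-nUK arrest ensemble run to escape (n=60)."""
    proto = s.ProtocolSpec(mode="arrest", nUK0=10, t_max=4000.0)
    return s.run_ensemble(proto, params, n=60, seed0=SUITE_SEED)


@pytest.fixture(scope="session")
def fixed_points_nuk10(params):
    return s.find_steady_states(params, 10.0)


def random_states(n, seed, scale=200.0):
    """Random nonnegative species vectors for property checks."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, scale, size=(n, 8))
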