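import numpy as np
import pytest

import slowflow as sf

DT = 2.0


@pytest.fixture(scope="session")
def default_spec():
    return sf.make_default_network_spec(seed=1)


@pytest.fixture(scope="session")
def default_ts(default_spec):
    """One emulated recording at the default scale (4 nodes, 237 samples,
    TR = 2 s, 20 realizations)."""
    return sf.simulate_var(default_spec, 237, 20, seed=1)


@pytest.fixture(scope="session")
def default_S(default_ts):
    return sf.spectral_matrix(default_ts)


@pytest.fixture(scope="session")
def unidirectional_spec():
    """2-node VAR with a slow-3 resonant source driving an AR(1) sink
    through a band-limited coupling (x -> y only)."""
    from slowflow.experiments import make_unidirectional_spec

    return make_unidirectional_spec(np.random.default_rng(7))


@pytest.fixture(scope="session")
def long_unidirectional_sim(unidirectional_spec):
    ts = sf.simulate_var(unidirectional_spec, 4096, 50, seed=7)
    S = sf.spectral_matrix(ts)
    return ts, S
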