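import numpy as np
import pytest

import afgc


@pytest.fixture(scope="session")
def chain3_net():
    return afgc.make_topology("chain3")


@pytest.fixture(scope="session")
def dual10_net():
    return afgc.make_topology("dual_chain10")


@pytest.fixture(scope="session")
def mini20_net():
    return afgc.make_topology("mini_scn20", seed=0)


@pytest.fixture(scope="session")
def chain3_traj(chain3_net):
    """One medium-length 3-cell simulation shared across tests."""
    params = afgc.SimulationParams(seed=11, t_end=160.0)
    return afgc.simulate(chain3_net, params)


@pytest.fixture(scope="session")
def chain3_panel(chain3_net):
    """6 h of rising-segment differences from the 3-cell chain."""
    params = afgc.SimulationParams(seed=11)
    return afgc.collect_panel(chain3_net, params, 6.0)


@pytest.fixture(scope="session")
def mini20_panel(mini20_net):
    """14 h of rising-segment differences from the 20-cell network."""
    params = afgc.SimulationParams(seed=3)
    return afgc.collect_panel(mini20_net, params, 14.0)


def make_white_panel(n, K, seed=0, boundaries=(), scale=1.0):
    """Independent Gaussian panel: the Granger null."""
    rng = np.random.default_rng(seed)
    return afgc.DifferencedPanel(
        values=scale * rng.standard_normal((n, K)),
        segment_boundaries=np.asarray(boundaries, dtype=int),
        sample_interval=1.0)


def make_var_panel(n, coefs, seed=0, sigma=1.0, intercept=0.0, burn=200):
    """Simulate a stationary VAR: coefs shape (p, K, K), coefs[l][j, i] is
    the effect of cell j at lag l+1 on cell i."""
    coefs = np.asarray(coefs, dtype=float)
    p, K, _ = coefs.shape
    rng = np.random.default_rng(seed)
    x = np.zeros((n + burn, K))
    for t in range(p, n + burn):
        acc = intercept + sigma * rng.standard_normal(K)
        for l in range(p):
            acc = acc + x[t - l - 1] @ coefs[l]
        x[t] = acc
    return afgc.DifferencedPanel(
        values=x[burn:], segment_boundaries=np.array([], dtype=int),
        sample_interval=1.0)


@pytest.fixture
def white_panel_factory():
    return make_white_panel


@pytest.fixture
def var_panel_factory():
    return make_var_panel
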