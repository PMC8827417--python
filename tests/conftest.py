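import numpy as np
import pytest

import sparsebalance as sb


@pytest.fixture(scope="session")
def small_chaotic_traj():
    """A modest high-variance gamma network run, shared across stats tests."""
    spec = sb.WeightSpec("gamma", J0=2.0, g=2.0, nu=0.5, K=400, N=400)
    W = sb.sample_weights(spec, seed=5, dtype=np.float32)
    cfg = sb.SimulationConfig(
        I0=1.0, dt=0.05, T=300.0, burn_in=50.0, record_stride=2, seed=6,
        dtype=np.float32,
    )
    traj = sb.simulate(W, sb.Nonlinearity("rect_tanh"), cfg)
    return spec, traj


@pytest.fixture(scope="session")
def heaviside_traj():
    """Heaviside gamma network used for the exact binary-rate identities."""
    spec = sb.WeightSpec("gamma", J0=2.0, g=2.0, nu=0.5, K=500, N=500)
    W = sb.sample_weights(spec, seed=11, dtype=np.float32)
    cfg = sb.SimulationConfig(
        I0=1.0, dt=0.05, T=300.0, burn_in=50.0, record_stride=2, seed=12,
        dtype=np.float32,
    )
    traj = sb.simulate(W, sb.Nonlinearity("heaviside"), cfg)
    return spec, traj
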