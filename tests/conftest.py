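import numpy as np
import pytest

from myxosim import ModelParams, validate_params


@pytest.fixture
def params():
    """Validated default parameter set on a small domain."""
    return validate_params(ModelParams(L_sim=40.0, t_end=5.0, seed=0))


@pytest.fixture
def quiet_params():
    """Small domain with all behavior/slime features off: pure mechanics."""
    return validate_params(ModelParams(
        L_sim=40.0, t_end=5.0, seed=0, reversals_enabled=False,
        turns_enabled=False, slime_enabled=False, adhesion_enabled=False))


def random_chain(rng, p, bend=0.3):
    """A mildly bent random N-node chain with bond lengths near l0."""
    from myxosim import AgentState

    theta = rng.uniform(0, 2 * np.pi)
    pos = [np.array([20.0, 20.0])]
    for _ in range(p.N - 1):
        theta += rng.uniform(-bend, bend)
        step = p.l0 * (1 + rng.uniform(-0.08, 0.08))
        pos.append(pos[-1] + step * np.array([np.cos(theta), np.sin(theta)]))
    a = AgentState.straight(np.array([20.0, 20.0]), 0.0, p)
    a.positions = np.array(pos)
    return a
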