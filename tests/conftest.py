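import numpy as np
import pytest

import selearn as sl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def schedule_cfg():
    return sl.ScheduleConfig()


@pytest.fixture
def assoc_params():
    return sl.AssocParams(
        variant="selfother_asym_3l",
        lambdas={"lam_self_pos": 0.3, "lam_self_neg": 0.4, "lam_other": 0.2},
        tau=0.3,
        rho=0.1,
        q0_pos=0.2,
    )


@pytest.fixture
def belief_params():
    return sl.BeliefParams(
        variant="selfother",
        alpha_trait={"self": 6.0, "other": 5.0},
        beta_trait={"self": 4.0, "other": 3.5},
        eta={"self": 0.85, "other": 0.85},
        tau=0.12,
        alpha_init=0.5,
        beta_init=0.5,
    )


@pytest.fixture
def assoc_sessions(assoc_params, schedule_cfg):
    rng = np.random.default_rng(77)
    return [
        sl.simulate_session(sl.AssocAgent(assoc_params), schedule_cfg, rng, f"p{i}", 20.0 + i)
        for i in range(6)
    ]


@pytest.fixture
def belief_sessions(belief_params, schedule_cfg):
    rng = np.random.default_rng(78)
    return [
        sl.simulate_session(sl.BeliefAgent(belief_params), schedule_cfg, rng, f"q{i}", 20.0 + i)
        for i in range(6)
    ]
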