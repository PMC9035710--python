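import numpy as np
import pytest

import revlearn as rl


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def task_config():
    return rl.TaskConfig()


@pytest.fixture
def group_mean_params():
    """Published group-mean dual-rate parameters."""
    return rl.DualRateParams(alpha_pos=0.4605, alpha_neg=0.9786, beta=1.8533)


@pytest.fixture(scope="session")
def sim_session():
    """One 360-trial session from a group-mean dual-rate agent."""
    params = rl.DualRateParams(alpha_pos=0.4605, alpha_neg=0.9786, beta=1.8533)
    rng = np.random.default_rng(7)
    return rl.run_session(rl.RLAgent(params), rl.TaskConfig(), rng, subject="demo")


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 8-subject cohort (full 360-trial sessions)."""
    cfg = rl.CohortConfig(n_subjects=8, seed=5)
    records, table = rl.generate_cohort(cfg)
    return cfg, records, table
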