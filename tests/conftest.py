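import numpy as np
import pytest

from adaptddm.ddm_fpe import FPEGrid
from adaptddm.synthetic_data import default_unadapted_params, simulate_trials
from adaptddm.trial_data import EXP1_STIMULUS_SET


@pytest.fixture(scope="session")
def base_params():
    """Paper-scale symmetric ground truth: B=1, dB=0, T0=0.35, slope 8."""
    return default_unadapted_params()


@pytest.fixture(scope="session")
def sim_table_6600(base_params):
    """600 trials per stimulus over the fixed 11-strength set (pooled scale)."""
    return simulate_trials(base_params, EXP1_STIMULUS_SET, 600, seed=11,
                           dt=1e-3)


@pytest.fixture(scope="session")
def coarse_grid():
    """Solver grid coarse enough for fast fits, accurate to ~1e-3 in P."""
    return FPEGrid(dv=0.02, dt=2.5e-3, t_max=6.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
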