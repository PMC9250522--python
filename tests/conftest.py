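import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import odorbarrel as ob
from odorbarrel.preprocess import compute_dff, epoch_average, neuropil_correct
from odorbarrel.synth import PopulationParams, simulate_population

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def protocol():
    """Default 150-trial, 9-condition olfacto-tactile protocol."""
    return ob.make_protocol(seed=11)


@pytest.fixture(scope="session")
def short_protocol():
    """A small, fast protocol (same 9 conditions, fewer reps, short trials)."""
    conds, _ = ob.protocol.default_conditions()
    reps = [2, 2, 2, 2, 4, 4, 4, 4, 6]
    return ob.make_protocol(conds, reps, seed=5, trial_duration_s=8.0, stim_onset_s=3.0)


@pytest.fixture(scope="session")
def null_session(protocol):
    """Effect-free session: no odor modulation, no odor identity signal."""
    params = PopulationParams(n_cells=120, frac_modulated=0.0, odor_identity_coef=0.0)
    fluor, gt = simulate_population(protocol, params, seed=21)
    return fluor, gt


@pytest.fixture(scope="session")
def null_epoch_means(protocol, null_session):
    fluor, _ = null_session
    dff = compute_dff(neuropil_correct(fluor.F, fluor.F_n), protocol)
    return epoch_average(dff, protocol.stim_epoch_s)


def gaussian_epoch_means(n_cells, n_trials, seed):
    """Plain iid stimulus-epoch means, the cheap stand-in for effect-free sessions."""
    return np.random.default_rng(seed).standard_normal((n_cells, n_trials))
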