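import numpy as np
import pytest

import synopt as sp


@pytest.fixture(scope="session")
def small_setup():
    """Forward-consistent synthetic trial at CI scale (m=12, d=6, f=51)."""
    params = sp.default_muscle_params(12, 1)
    plant = sp.generate_plant(12, 6, 51, 0.01, seed=1, params=params)
    gt = sp.generate_ground_truth(3, 51, 12, seed=1, plant=plant, params=params)
    trial = sp.forward_consistent_trial(plant, gt, params)
    return trial, gt, params


@pytest.fixture(scope="session")
def so_solution(small_setup):
    """SO activations and the moments they produce, shared across tests."""
    trial, _, params = small_setup
    a = sp.solve_trial(trial, params, sp.SOConfig(seed=1))
    q = sp.compute_joint_moments(
        sp.compute_muscle_forces(a, trial.lmt, trial.vmt, params), trial.moment_arms
    )
    return a, q


@pytest.fixture
def unit_frame():
    """One-DOF, two-identical-muscle frame with unit curves (analytic oracle).

    Gain per muscle is f_max * r = 1000 N * 0.05 m = 50 N*m per unit
    activation, so a symmetric demand q splits as a_i = q / 100.
    """
    params = sp.MuscleParams(
        f_max=np.array([1000.0, 1000.0]),
        l0=np.array([0.1, 0.1]),
        lts=np.array([0.0, 0.0]),
        alpha0=np.zeros(2),
        vmax=np.full(2, 10.0),
        passive_enabled=False,
    )
    r_j = np.array([[0.05, 0.05]])  # (d=1, m=2)
    lmt_j = np.array([0.1, 0.1])
    vmt_j = np.zeros(2)
    return params, r_j, lmt_j, vmt_j
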