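import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import synopt as sp
from synopt.exceptions import InvalidArgumentError
from synopt.muscle_model import UNIT_CURVES
from synopt.synergy_optimization import (
    BSplineControl,
    fit_nodes_to_profiles,
    node_count,
    spline_basis,
)


def _one_frame_trial(q):
    return sp.TrialData(
        dt=0.01, dof_labels=["d1"], muscle_labels=["m1"],
        moment_arms=np.array([[[0.05]]]), lmt=np.array([[0.1]]),
        vmt=np.array([[0.0]]), q_id=np.array([[q]]),
    )


def _one_muscle_params():
    return sp.MuscleParams(
        f_max=np.array([1000.0]), l0=np.array([0.1]), lts=np.array([0.0]),
        alpha0=np.array([0.0]), vmax=np.array([10.0]), passive_enabled=False,
    )


class TestNodeCount:
    @pytest.mark.parametrize("f,expected", [(101, 21), (1, 1), (6, 2), (11, 3), (13, 3), (14, 4)])
    def test_printed_formula_with_half_up_rounding(self, f, expected):
        assert node_count(f) == expected

    def test_invalid_frame_count_rejected(self):
        with pytest.raises(InvalidArgumentError):
            node_count(0)


class TestSplineActivations:
    def test_partition_of_unity_constant_nodes_give_constant_profile(self):
        ctrl = BSplineControl(nodes=np.full((8, 2), 0.4), duration=1.0)
        C = sp.evaluate_synergy_activations(ctrl, 41, dt=0.025)
        assert np.allclose(C, 0.4, atol=1e-12)

    def test_nonnegative_nodes_give_nonnegative_profile(self):
        rng = np.random.default_rng(0)
        ctrl = BSplineControl(nodes=rng.uniform(0, 1, (11, 3)))
        C = sp.evaluate_synergy_activations(ctrl, 51, dt=0.02)
        assert C.min() >= -1e-15

    def test_node_perturbation_is_local_to_its_support(self):
        f, p, k = 101, 21, 3
        B = spline_basis(f, p, k, dt=0.01)
        base = np.random.default_rng(1).uniform(0, 1, (p, 1))
        bumped = base.copy()
        bumped[10, 0] += 0.5
        diff = (B @ bumped - B @ base)[:, 0]
        support = B[:, 10] > 0
        assert np.all(diff[~support] == 0)
        assert np.any(diff[support] > 0)

    def test_negative_nodes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            BSplineControl(nodes=np.array([[-0.1], [0.2], [0.3], [0.4]]))

    def test_too_few_nodes_for_degree_rejected(self):
        ctrl = BSplineControl(nodes=np.full((2, 1), 0.5), degree=3)
        with pytest.raises(InvalidArgumentError, match="degree"):
            sp.evaluate_synergy_activations(ctrl, 10)


class TestConstructActivations:
    def test_hand_matrix_product(self):
        C = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        V = np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.25, 0.75]])
        expected = np.array(
            [[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.5, 1.5], [0.5, 0.5, 0.25, 0.75]]
        )
        assert np.allclose(sp.construct_activations(C, V), expected, atol=1e-15)

    def test_zero_and_uniform_cases(self):
        assert np.all(sp.construct_activations(np.zeros((4, 2)), np.ones((2, 3))) == 0)
        a = sp.construct_activations(np.ones((5, 1)), np.full((1, 4), 0.25))
        assert np.allclose(a, 0.25)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sp.construct_activations(np.ones((3, 2)), np.ones((3, 4)))


class TestSynoObjective:
    def test_effort_only_cost_at_perfect_moment_match(self):
        # a = 0.5 produces Q = 0.05 * 1000 * 0.5 = 25 N*m = Q^ID: cost = a^2
        trial = _one_frame_trial(25.0)
        cost = sp.syno_objective(np.array([0.5, 1.0]), trial, _one_muscle_params(),
                                 n_s=1, curves=UNIT_CURVES)
        assert cost == pytest.approx(0.25, abs=1e-12)

    def test_penalty_applied_above_unit_activation(self):
        trial = _one_frame_trial(60.0)  # matched by a = 1.2
        cost = sp.syno_objective(np.array([1.2, 1.0]), trial, _one_muscle_params(),
                                 n_s=1, curves=UNIT_CURVES)
        assert cost == pytest.approx(1.44 + 1e5 * 0.04, rel=1e-12)

    def test_zero_activation_zero_moment_zero_cost_with_normalizer_fallback(self):
        trial = _one_frame_trial(0.0)
        with pytest.warns(UserWarning, match="normalizer"):
            cost = sp.syno_objective(np.array([0.0, 1.0]), trial, _one_muscle_params(),
                                     n_s=1, curves=UNIT_CURVES)
        assert cost == 0.0

    def test_gradient_matches_finite_differences(self, small_setup):
        trial, _, params = small_setup
        from synopt.synergy_optimization import _SynOProblem

        prob = _SynOProblem(trial, params, 2, sp.SynOConfig(seed=0), sp.DEFAULT_CURVES)
        rng = np.random.default_rng(5)
        x = rng.uniform(0.01, 1.0, prob.n_design)
        cost, grad = prob.cost_grad(x)
        eps = 1e-6
        for idx in rng.choice(prob.n_design, 8, replace=False):
            xp = x.copy()
            xp[idx] += eps
            fd = (prob.cost_grad(xp)[0] - cost) / eps
            assert grad[idx] == pytest.approx(fd, rel=5e-4, abs=1e-5)


class TestSolveSyno:
    def test_recovers_ground_truth_synergies(self, small_setup):
        trial, gt, params = small_setup
        syn, a, diag = sp.solve_syno(trial, params, 3, sp.SynOConfig(seed=1))
        # per-DOF moment tracking
        assert diag["vaf_per_dof"].min() >= 99.0
        # permutation-matched cosine similarity of synergy vectors
        Vt = gt.V / np.linalg.norm(gt.V, axis=1, keepdims=True)
        Vr = syn.V / np.linalg.norm(syn.V, axis=1, keepdims=True)
        cos = Vt @ Vr.T
        rows, cols = linear_sum_assignment(-cos)
        assert cos[rows, cols].min() >= 0.9
        # constraint satisfaction
        assert np.allclose(syn.V.sum(axis=1), 1.0, atol=1e-6)
        assert syn.V.min() >= 0 and syn.C.min() >= 0 and a.min() >= 0

    def test_solution_cost_bounded_by_ground_truth_cost(self, small_setup):
        trial, gt, params = small_setup
        _, _, diag = sp.solve_syno(trial, params, 3, sp.SynOConfig(seed=1))
        nodes_gt = fit_nodes_to_profiles(gt.C, trial.dt)
        x_gt = np.concatenate([nodes_gt.ravel(), gt.V.ravel()])
        cost_gt = sp.syno_objective(x_gt, trial, params, 3)
        assert diag["cost"] <= cost_gt + 1e-6

    def test_cost_non_increasing_in_synergy_count(self, small_setup):
        trial, _, params = small_setup
        costs = [
            sp.solve_syno(trial, params, n_s, sp.SynOConfig(seed=1, n_multistarts=3))[2]["cost"]
            for n_s in (2, 3, 4)
        ]
        assert costs[0] >= costs[1] >= costs[2]

    def test_deterministic_under_fixed_seed(self, small_setup):
        trial, _, params = small_setup
        cfg = sp.SynOConfig(seed=4, n_multistarts=2, max_iter=150)
        _, a1, d1 = sp.solve_syno(trial, params, 2, cfg)
        _, a2, d2 = sp.solve_syno(trial, params, 2, cfg)
        assert np.array_equal(a1, a2)
        assert d1["cost"] == d2["cost"]

    def test_missing_moments_rejected(self, small_setup):
        _, _, params = small_setup
        plant = sp.generate_plant(12, 6, 51, seed=1)
        with pytest.raises(InvalidArgumentError, match="q_id"):
            sp.solve_syno(plant, params, 2)
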