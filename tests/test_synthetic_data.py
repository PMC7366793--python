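import numpy as np
import pytest

import synopt as sp
from synopt.exceptions import InvalidArgumentError
from synopt.synthetic_data import MAX_MOMENT_ARM


class TestGeneratePlant:
    def test_identical_seed_bit_identical_output(self):
        a = sp.generate_plant(43, 6, 101, seed=7)
        b = sp.generate_plant(43, 6, 101, seed=7)
        assert np.array_equal(a.moment_arms, b.moment_arms)
        assert np.array_equal(a.lmt, b.lmt)
        assert np.array_equal(a.vmt, b.vmt)
        c = sp.generate_plant(43, 6, 101, seed=8)
        assert not np.array_equal(a.moment_arms, c.moment_arms)

    def test_velocity_is_derivative_of_length(self):
        # central-difference residual must vanish quadratically in dt,
        # which holds only if vmt is the true analytic derivative of lmt
        def residual(f, dt):
            trial = sp.generate_plant(10, 3, f, dt=dt, seed=2)
            central = (trial.lmt[2:] - trial.lmt[:-2]) / (2 * dt)
            return np.abs(trial.vmt[1:-1] - central).max(), np.abs(trial.vmt).max()

        err_coarse, vmax = residual(101, 0.01)
        err_fine, _ = residual(1001, 0.001)  # same trajectory, 10x finer grid
        assert err_coarse < 1e-2 * vmax
        assert err_fine < err_coarse / 25

    def test_shapes_and_moment_arm_bound(self):
        trial = sp.generate_plant(2, 1, 10, seed=1)
        assert trial.moment_arms.shape == (10, 1, 2)
        assert np.abs(trial.moment_arms).max() <= MAX_MOMENT_ARM
        assert np.all(trial.lmt > 0)

    def test_lengths_stay_above_tendon_slack(self):
        params = sp.default_muscle_params(20, 9)
        trial = sp.generate_plant(20, 6, 51, seed=9, params=params)
        assert np.all(trial.lmt > params.lts[None, :])

    @pytest.mark.parametrize("m,d,f", [(0, 1, 10), (3, 0, 10), (5, 2, 1), (2, 3, 10)])
    def test_invalid_dimensions_rejected(self, m, d, f):
        with pytest.raises(InvalidArgumentError):
            sp.generate_plant(m, d, f, seed=0)


class TestGenerateGroundTruth:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_synergy_vector_rows_sum_to_one(self, seed):
        gt = sp.generate_ground_truth(4, 51, 10, seed=seed)
        assert np.allclose(gt.V.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(gt.V >= 0) and np.all(gt.C >= 0)

    def test_activations_are_exact_product_and_bounded(self):
        gt = sp.generate_ground_truth(3, 101, 43, seed=5)
        assert np.array_equal(gt.true_activations, gt.C @ gt.V)
        assert gt.true_activations.min() >= 0
        assert gt.true_activations.max() <= 1.0

    def test_rank_one_structure_for_single_synergy(self):
        gt = sp.generate_ground_truth(1, 51, 8, seed=3)
        a = gt.true_activations
        # every muscle column proportional to the single synergy activation
        for i in range(8):
            assert np.allclose(a[:, i], gt.C[:, 0] * gt.V[0, i], atol=1e-15)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_numerical_rank_equals_synergy_count(self, seed):
        gt = sp.generate_ground_truth(3, 51, 12, seed=seed)
        s = np.linalg.svd(gt.true_activations, compute_uv=False)
        assert np.sum(s > 1e-10 * s[0]) == 3

    def test_effort_aware_vectors_also_normalized(self):
        params = sp.default_muscle_params(12, 4)
        plant = sp.generate_plant(12, 6, 51, seed=4, params=params)
        gt = sp.generate_ground_truth(3, 51, 12, seed=4, plant=plant, params=params)
        assert np.allclose(gt.V.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(gt.V >= 0)

    def test_too_many_synergies_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sp.generate_ground_truth(13, 51, 12, seed=0)


class TestForwardConsistentTrial:
    def test_ground_truth_reproduces_moments_exactly(self, small_setup):
        trial, gt, params = small_setup
        q = sp.compute_joint_moments(
            sp.compute_muscle_forces(gt.true_activations, trial.lmt, trial.vmt, params),
            trial.moment_arms,
        )
        assert np.array_equal(q, trial.q_id)

    def test_zero_activation_without_passive_gives_zero_moments(self):
        params = sp.default_muscle_params(6, 2, passive_enabled=False)
        plant = sp.generate_plant(6, 2, 21, seed=2, params=params)
        gt = sp.generate_ground_truth(2, 21, 6, seed=2)
        gt.true_activations[:] = 0.0
        trial = sp.forward_consistent_trial(plant, gt, params)
        assert np.all(trial.q_id == 0)

    def test_dimension_mismatch_rejected(self, small_setup):
        trial, gt, params = small_setup
        bad_gt = sp.generate_ground_truth(3, 21, 12, seed=1)
        with pytest.raises(InvalidArgumentError):
            sp.forward_consistent_trial(trial, bad_gt, params)


class TestSynthesizeEmg:
    def test_identity_channel_correlates_perfectly_at_zero_lag(self, small_setup):
        # zero delay, zero noise, identity crosstalk: the raw channel sampled
        # at the frame times IS the true activation
        trial, gt, _ = small_setup
        emg = sp.synthesize_emg(gt, trial, [trial.muscle_labels[0]], seed=0)
        step = int(round(emg.sample_rate * trial.dt))
        raw_at_frames = emg.channels[0, ::step][: trial.n_frames]
        r, lag = sp.lagged_pearson(gt.true_activations[:, 0], raw_at_frames, trial.dt)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert lag == 0.0

    def test_envelope_of_identity_channel_tracks_activation(self, small_setup):
        trial, gt, _ = small_setup
        emg = sp.synthesize_emg(gt, trial, [trial.muscle_labels[0]], seed=0)
        env = sp.resample_to_frames(sp.process_emg(emg), trial.n_frames, trial.dt)
        r, lag = sp.lagged_pearson(gt.true_activations[:, 0], env[0], trial.dt)
        assert r > 0.99
        assert lag == 0.0

    def test_injected_delay_recovered_by_lagged_correlation(self, small_setup):
        trial, gt, _ = small_setup
        emg = sp.synthesize_emg(
            gt, trial, [trial.muscle_labels[0]], delays=[0.04], seed=0
        )
        env = sp.process_emg(emg)
        resampled = sp.resample_to_frames(env, trial.n_frames, trial.dt)
        r, lag = sp.lagged_pearson(gt.true_activations[:, 0], resampled[0], trial.dt)
        assert r > 0.99
        assert lag == pytest.approx(40.0, abs=trial.dt * 1000 / 2)

    def test_crosstalk_strictly_degrades_own_source_correlation(self, small_setup):
        # plant two muscles with disjoint burst profiles so mixing is visible
        trial, _, _ = small_setup
        phi = np.linspace(0, 1, trial.n_frames)
        C = np.column_stack([
            np.exp(-0.5 * ((phi - 0.25) / 0.08) ** 2),
            np.exp(-0.5 * ((phi - 0.75) / 0.08) ** 2),
        ])
        V = np.zeros((2, trial.n_muscles))
        V[0, 0] = 1.0
        V[1, 1] = 1.0
        gt = sp.GroundTruth(C=C, V=V, true_activations=C @ V, seed=3)
        chans = [trial.muscle_labels[0], trial.muscle_labels[1]]
        clean = sp.synthesize_emg(gt, trial, chans, seed=3)
        mixed = sp.synthesize_emg(
            gt, trial, chans, crosstalk=np.array([[1.0, 0.3], [0.3, 1.0]]), seed=3
        )
        f, dt = trial.n_frames, trial.dt
        step = int(round(clean.sample_rate * dt))
        r_clean, _ = sp.lagged_pearson(
            gt.true_activations[:, 0], clean.channels[0, ::step][:f], dt)
        r_mixed, _ = sp.lagged_pearson(
            gt.true_activations[:, 0], mixed.channels[0, ::step][:f], dt)
        assert r_mixed < r_clean
        assert r_clean == pytest.approx(1.0, abs=1e-12)

    def test_seeded_noise_is_deterministic(self, small_setup):
        trial, gt, _ = small_setup
        kw = dict(noise_sd=0.1, seed=11)
        a = sp.synthesize_emg(gt, trial, [trial.muscle_labels[2]], **kw)
        b = sp.synthesize_emg(gt, trial, [trial.muscle_labels[2]], **kw)
        assert np.array_equal(a.channels, b.channels)
        assert np.all(a.channels >= 0)  # rectified

    def test_unknown_muscle_rejected(self, small_setup):
        trial, gt, _ = small_setup
        with pytest.raises(InvalidArgumentError, match="unknown muscle"):
            sp.synthesize_emg(gt, trial, ["not_a_muscle"], seed=0)
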