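import numpy as np
import pytest

from cortexlimb import synthetic_data as sd
from cortexlimb.arm_kinematics import (
    inverse_kinematics,
    summed_squared_velocity,
)
from cortexlimb.emg_processing import emg_envelope
from cortexlimb.exceptions import ConfigurationError


class TestTaskTrajectory:
    def test_holds_are_stationary(self, small_session):
        config, _, _ = small_session
        ang, _ = sd.generate_task_trajectory("CAB", config, np.random.default_rng(1))
        ssv = summed_squared_velocity(ang)
        assert np.max(ssv[ang.times < -0.05]) < 1e-6  # initial hold
        # the final hold (last ~0.5 s of the trial) is stationary too
        assert np.max(ssv[ang.times > config.task.trial_s - 0.5]) < 1e-6

    def test_trial_sample_count(self, small_session):
        config, _, _ = small_session
        ang, _ = sd.generate_task_trajectory("CDB", config, np.random.default_rng(2))
        task_samples = np.sum(ang.times >= 0)
        assert task_samples == round(4.503 * 1000) == 4503

    def test_seeded_determinism_and_jitter(self, small_session):
        config, _, _ = small_session
        a1, _ = sd.generate_task_trajectory("DBA", config, np.random.default_rng(5))
        a2, _ = sd.generate_task_trajectory("DBA", config, np.random.default_rng(5))
        a3, _ = sd.generate_task_trajectory("DBA", config, np.random.default_rng(6))
        np.testing.assert_array_equal(a1.theta, a2.theta)
        assert not np.array_equal(a1.theta, a3.theta)  # start-time jitter

    def test_markers_invert_to_angles(self, small_session):
        config, _, _ = small_session
        ang, mk = sd.generate_task_trajectory("DCA", config, np.random.default_rng(3))
        back = inverse_kinematics(mk, config.geometry)
        # markers are FK of the same trajectory evaluated on the marker grid
        sub = ang.theta[:, :: int(ang.rate // mk.rate)]
        assert back.theta.shape[1] == mk.n_samples
        assert np.max(np.abs(back.theta[:, 0] - ang.theta[:, 0])) < 1e-9

    def test_unknown_sequence_rejected(self, small_session):
        config, _, _ = small_session
        with pytest.raises(ConfigurationError):
            sd.generate_task_trajectory("XYZ", config, np.random.default_rng(0))

    def test_buttons_reachable_at_70pct_extension(self, small_session):
        config, _, _ = small_session
        from cortexlimb.arm_kinematics import JointAngleTrajectory, forward_kinematics

        reach = config.geometry.l1 + config.geometry.l2
        for name, theta in sd.BUTTON_POSTURES.items():
            mk = forward_kinematics(
                JointAngleTrajectory(theta=theta[:, None], rate=1.0), config.geometry
            )
            frac = np.linalg.norm(mk.wrist[:, 0]) / reach
            assert 0.6 < frac < 0.8


class TestMuscleActivations:
    def test_channel_count_and_nonnegativity(self, small_session):
        config, _, _ = small_session
        ang, _ = sd.generate_task_trajectory("CAB", config, np.random.default_rng(1))
        act = sd.muscle_activations(ang, config)
        assert act.shape[0] == 9
        assert np.all(act >= config.tonic_floor - 1e-12)

    def test_static_hold_at_reference_gives_tonic_floor(self, small_session):
        config, _, _ = small_session
        from cortexlimb.arm_kinematics import JointAngleTrajectory

        theta = np.tile(sd.BUTTON_POSTURES["hold"][:, None], (1, 500))
        act = sd.muscle_activations(
            JointAngleTrajectory(theta=theta, rate=1000.0), config
        )
        np.testing.assert_allclose(act, config.tonic_floor)

    def test_elbow_flexion_drives_flexors_over_extensors(self, small_session):
        config, _, _ = small_session
        from cortexlimb.arm_kinematics import JointAngleTrajectory

        T = 1000
        theta = np.tile(sd.BUTTON_POSTURES["hold"][:, None], (1, T))
        theta[3] = np.linspace(1.567, 1.0, T)  # theta4 decreasing: flexion
        act = sd.muscle_activations(
            JointAngleTrajectory(theta=theta, rate=1000.0), config
        )
        biceps, brachialis = act[5].mean(), act[6].mean()
        tri_long, tri_lat = act[7].mean(), act[8].mean()
        assert biceps > tri_long and brachialis > tri_lat


class TestSynthesizeEmg:
    def test_zero_activation_leaves_configured_noise_floor(self, rng):
        act = np.zeros((9, 20000))
        raw = sd.synthesize_emg(act, 1000.0, snr=10.0, rng=rng, noise_ref=0.2)
        expected_var = (0.2 / np.sqrt(10.0)) ** 2
        assert abs(np.var(raw.samples) - expected_var) / expected_var < 0.1

    def test_envelope_tracks_activation(self, small_session, rng):
        config, _, _ = small_session
        ang, _ = sd.generate_task_trajectory("CAB", config, np.random.default_rng(1))
        act = sd.muscle_activations(ang, config)
        raw = sd.synthesize_emg(act, 1000.0, snr=10.0, rng=rng)
        env = emg_envelope(raw)
        ccs = [np.corrcoef(env[m], act[m])[0, 1] for m in range(9)]
        assert np.mean(ccs) > 0.9

    def test_modulation_is_linear_in_activation(self, small_session):
        config, _, _ = small_session
        ang, _ = sd.generate_task_trajectory("CAB", config, np.random.default_rng(1))
        act = sd.muscle_activations(ang, config)
        r1 = sd.synthesize_emg(act, 1000.0, 1e9, np.random.default_rng(9))
        r2 = sd.synthesize_emg(2 * act, 1000.0, 1e9, np.random.default_rng(9))
        a1 = emg_envelope(r1).mean()
        a2 = emg_envelope(r2).mean()
        assert abs(a2 / a1 - 2.0) < 0.05


class TestSourcesAndEEG:
    def test_cortex_muscle_model_exact_at_lag(self, small_session):
        """The constructed currents satisfy the delayed linear EMG model."""
        _, session, truth = small_session
        W = sd.true_emg_weights(truth.mixing)
        for tr in session.trials[:3]:
            J, femg = tr.truth["j_m1"], tr.truth["femg"]
            d = truth.delay_samples
            np.testing.assert_allclose(
                (W @ J)[:, :-d], femg[:, d:], atol=1e-10
            )

    def test_noiseless_eeg_lies_in_leadfield_column_space(self, small_session):
        config, session, _ = small_session
        G = session.lead_field.G
        # project a clean regeneration onto the column space of G
        rng = np.random.default_rng(0)
        cfg = sd.SimulationConfig.test_scale(eeg_snr=1e12)
        s2, _ = sd.generate_session(cfg, seed=99)
        E = s2.trials[0].eeg.samples
        Gq, _ = np.linalg.qr(s2.lead_field.G)
        resid = E - Gq @ (Gq.T @ E)
        assert np.linalg.norm(resid) / np.linalg.norm(E) < 1e-6

    def test_heart_amplitude_raises_projected_power(self):
        powers = []
        for amp in (0.5, 2.0, 8.0):
            cfg = sd.SimulationConfig.test_scale(heart_amp=amp)
            session, _ = sd.generate_session(cfg, seed=42)
            lf = session.lead_field
            heart_col = lf.G[:, lf.artifact_idx[0]]
            u = heart_col / np.linalg.norm(heart_col)
            E = session.trials[0].eeg.samples
            powers.append(float(np.mean((u @ E) ** 2)))
        assert powers[0] < powers[1] < powers[2]


class TestLeadField:
    def test_fmri_prior_max_is_one_on_m1(self, small_session):
        _, session, _ = small_session
        t = session.fmri_prior.t_hat
        assert t.max() == 1.0
        assert t[session.lead_field.roi_m1].min() > 0.5
        off_m1 = np.setdiff1d(np.arange(len(t)), session.lead_field.roi_m1)
        assert np.median(t[off_m1]) < 0.1

    def test_sphere_model_depth_monotonicity(self):
        sensors = sd._fibonacci_hemisphere(16, 0.1)
        norms = []
        for b in (0.03, 0.05, 0.069):
            G = sd.three_sphere_lead_field(
                sensors, np.array([[0.0, 0.0, b]]), np.array([[1.0, 0.0, 0.0]])
            )
            norms.append(np.linalg.norm(G))
        assert norms[0] < norms[1] < norms[2]

    def test_sphere_source_outside_brain_rejected(self):
        sensors = sd._fibonacci_hemisphere(8, 0.1)
        with pytest.raises(ConfigurationError):
            sd.three_sphere_lead_field(
                sensors, np.array([[0.0, 0.0, 0.09]]), np.array([[1.0, 0.0, 0.0]])
            )

    def test_same_seed_same_leadfield(self):
        cfg = sd.SimulationConfig.test_scale()
        g1 = sd.synth_lead_field(cfg, np.random.default_rng(4)).G
        g2 = sd.synth_lead_field(cfg, np.random.default_rng(4)).G
        np.testing.assert_array_equal(g1, g2)

    def test_region_labels_partition(self, small_session):
        _, session, _ = small_session
        lf = session.lead_field
        assert set(lf.regions) == {"M1", "PMd", "PP", "All"}
        np.testing.assert_array_equal(lf.regions["M1"], lf.roi_m1)
        assert len(np.intersect1d(lf.regions["M1"], lf.regions["PMd"])) == 0


class TestSession:
    def test_trial_counts_per_sequence(self, small_session):
        config, session, _ = small_session
        assert len(session.trials) == config.n_sets * 4 * config.trials_per_sequence
        for task in sd.SEQUENCES:
            n = sum(tr.task == task for tr in session.trials)
            assert n == config.n_sets * config.trials_per_sequence

    def test_default_config_session_arithmetic(self):
        """7 sets x 40 trials, 70 per sequence (computed, not generated)."""
        cfg = sd.SimulationConfig()
        total = cfg.n_sets * 4 * cfg.trials_per_sequence
        per_seq = cfg.n_sets * cfg.trials_per_sequence
        assert total == 280 and per_seq == 70

    def test_sessions_bitwise_reproducible(self, small_session):
        config, session, _ = small_session
        again, _ = sd.generate_session(config, seed=11)
        for a, b in zip(session.trials, again.trials):
            np.testing.assert_array_equal(a.eeg.samples, b.eeg.samples)
            np.testing.assert_array_equal(a.emg.samples, b.emg.samples)

    def test_manifest_records_config_and_seed(self, small_session):
        config, session, _ = small_session
        m = session.config["manifest"]
        assert m["seed"] == 11
        assert m["config_sha1"] == config.manifest(11)["config_sha1"]


class TestRegimeSwitchingData:
    def test_shapes_and_regime_structure(self):
        u, ang, feat, regime = sd.generate_regime_switching_data(0)
        assert u.shape == (3000, 9) and ang.theta.shape == (4, 3000)
        assert set(np.unique(regime)) == {0, 1}
        assert feat[regime == 1].min() > feat[regime == 0].max()

    def test_maps_differ_between_regimes(self):
        u, ang, feat, regime = sd.generate_regime_switching_data(1, noise=0.0)
        # the same input statistics produce opposite-sign outputs by regime
        y = ang.theta.T
        r0 = y[regime == 0] / np.maximum(u[regime == 0] @ np.ones(9), 1e-9)[:, None]
        r1 = y[regime == 1] / np.maximum(u[regime == 1] @ np.ones(9), 1e-9)[:, None]
        assert np.sign(np.mean(r0)) != np.sign(np.mean(r1))
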