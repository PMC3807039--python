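import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexlimb import modular_ann as ma
from cortexlimb.arm_kinematics import JointAngleTrajectory
from cortexlimb.exceptions import InvalidInputError, ModelStateError
from cortexlimb.synthetic_data import generate_regime_switching_data


def _instance(rng, T=6, N=2):
    scores = rng.normal(0, 2, (T, N))
    outs = rng.normal(0, 1, (N, T, 4))
    targets = rng.normal(0, 1, (T, 4))
    sigma = rng.uniform(0.5, 2.0, N)
    return scores, outs, targets, sigma


class TestSoftmaxGate:
    def test_symmetric_scores_split_evenly(self):
        np.testing.assert_allclose(ma.softmax_gate([0.0, 0.0]), [0.5, 0.5])

    def test_extreme_scores_stay_finite(self):
        g = ma.softmax_gate([100.0, 0.0])
        assert np.isclose(g[0], 1.0)
        assert np.isclose(g[1], 3.72e-44, rtol=1e-2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-700, 700), min_size=2, max_size=6))
    def test_outputs_sum_to_one(self, x):
        assert abs(ma.softmax_gate(x).sum() - 1.0) < 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            ma.softmax_gate([np.inf, 0.0])


class TestCombineExperts:
    def test_pure_expert(self, rng):
        outs = rng.standard_normal((2, 5, 4))
        g = np.tile([1.0, 0.0], (5, 1))
        np.testing.assert_allclose(ma.combine_experts(g, outs), outs[0])

    def test_opposite_experts_cancel(self, rng):
        a = rng.standard_normal((5, 4))
        outs = np.stack([a, -a])
        g = np.full((5, 2), 0.5)
        np.testing.assert_allclose(ma.combine_experts(g, outs), 0, atol=1e-12)

    def test_identical_experts_ignore_gate(self, rng):
        a = rng.standard_normal((5, 4))
        outs = np.stack([a, a])
        g = rng.dirichlet([1, 1], 5)
        np.testing.assert_allclose(ma.combine_experts(g, outs), a)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            ma.combine_experts(np.ones((5, 3)), rng.standard_normal((2, 5, 4)))


class TestMixtureLoglik:
    def test_perfect_fit_unit_weight_gives_zero(self):
        outs = np.zeros((2, 3, 4))
        targets = np.zeros((3, 4))
        scores = np.tile([50.0, -50.0], (3, 1))  # g ~ (1, 0)
        lnL, _ = ma.mixture_loglik(scores, outs, targets, np.array([1.0, 1.0]))
        np.testing.assert_allclose(lnL, 0.0, atol=1e-12)

    def test_responsibilities_sum_to_one(self, rng):
        scores, outs, targets, sigma = _instance(rng, T=20, N=3)
        _, resp = ma.mixture_loglik(scores, outs, targets, sigma)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0)

    def test_identical_experts_give_gate_responsibilities(self, rng):
        out = rng.standard_normal((1, 10, 4))
        outs = np.repeat(out, 2, axis=0)
        scores = rng.normal(0, 2, (10, 2))
        targets = rng.standard_normal((10, 4))
        _, resp = ma.mixture_loglik(scores, outs, targets, np.array([1.3, 1.3]))
        np.testing.assert_allclose(resp, ma.softmax_gate(scores), atol=1e-12)

    def test_extreme_residuals_never_nan(self, rng):
        scores = np.array([[300.0, -300.0]])
        outs = np.stack([np.full((1, 4), 1e6), np.zeros((1, 4))])
        lnL, resp = ma.mixture_loglik(
            scores, outs, np.zeros((1, 4)), np.array([0.1, 0.1])
        )
        assert np.all(np.isfinite(lnL)) and np.all(np.isfinite(resp))

    def test_sigma_must_be_positive(self, rng):
        scores, outs, targets, _ = _instance(rng)
        with pytest.raises(InvalidInputError):
            ma.mixture_loglik(scores, outs, targets, np.array([1.0, 0.0]))


class TestMixtureGradients:
    def test_gate_gradient_sums_to_zero(self, rng):
        scores, outs, targets, sigma = _instance(rng, T=30, N=3)
        ds, _ = ma.mixture_gradients(scores, outs, targets, sigma)
        np.testing.assert_allclose(ds.sum(axis=1), 0.0, atol=1e-12)

    def test_identical_experts_stationary_in_outputs(self, rng):
        out = rng.standard_normal((1, 8, 4))
        outs = np.repeat(out, 2, axis=0)
        scores = np.zeros((8, 2))
        # target equals the combined output -> expert gradients vanish
        _, do = ma.mixture_gradients(scores, outs, out[0], np.array([1.0, 1.0]))
        np.testing.assert_allclose(do, 0.0, atol=1e-12)

    def test_matches_finite_differences(self):
        """Analytic gate/expert gradients vs central differences."""
        max_err = 0.0
        for trial in range(100):
            rng = np.random.default_rng(trial)
            scores, outs, targets, sigma = _instance(rng, T=4, N=2 + trial % 2)
            ds, do = ma.mixture_gradients(scores, outs, targets, sigma)
            eps = 1e-5

            def lnl(s, o):
                return ma.mixture_loglik(s, o, targets, sigma)[0].sum()

            for idx in [(0, 0), (2, 1), (3, ds.shape[1] - 1)]:
                sp = scores.copy(); sp[idx] += eps
                sm = scores.copy(); sm[idx] -= eps
                num = (lnl(sp, outs) - lnl(sm, outs)) / (2 * eps)
                max_err = max(
                    max_err, abs(num - ds[idx]) / max(1.0, abs(num), abs(ds[idx]))
                )
            for idx in [(0, 1, 2), (do.shape[0] - 1, 3, 0)]:
                op = outs.copy(); op[idx] += eps
                om = outs.copy(); om[idx] -= eps
                num = (lnl(scores, op) - lnl(scores, om)) / (2 * eps)
                max_err = max(
                    max_err, abs(num - do[idx]) / max(1.0, abs(num), abs(do[idx]))
                )
        assert max_err < 1e-5


class TestTraining:
    def _separable(self, seed):
        return generate_regime_switching_data(seed, n_samples=2500, block_len=250)

    def test_gate_specializes_on_separable_regimes(self):
        u, ang, feat, regime = self._separable(0)
        model = ma.train_mixture(
            u, ang, ma.TrainConfig(epochs=1500, seed=0), gate_feature=feat
        )
        _, g = model.predict_standardized(u, feat)
        assert g[regime == 0].mean(axis=0)[0] >= 0.9  # posture -> expert 0
        assert g[regime == 1].mean(axis=0)[1] >= 0.9  # movement -> expert 1

    def test_zero_velocity_data_saturates_posture_expert(self, rng):
        T = 800
        u = np.abs(rng.normal(0.4, 0.1, (T, 9)))
        Y = (u @ rng.normal(0, 0.5, (9, 4))).T
        ang = JointAngleTrajectory(theta=Y, rate=100.0)
        feat = np.zeros(T)
        model = ma.train_mixture(
            u, ang, ma.TrainConfig(epochs=500, seed=1), gate_feature=feat
        )
        _, g = model.predict_standardized(u, feat)
        assert g[:, 0].mean() > 0.6  # gate prefers the posture expert

    def test_fixed_seed_training_is_bitwise_deterministic(self):
        u, ang, feat, _ = self._separable(3)
        cfg = ma.TrainConfig(epochs=100, seed=7)
        m1 = ma.train_mixture(u, ang, cfg, gate_feature=feat)
        m2 = ma.train_mixture(u, ang, cfg, gate_feature=feat)
        for p1, p2 in zip(m1.experts[0].params(), m2.experts[0].params()):
            np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(m1.gate.w, m2.gate.w)
        np.testing.assert_array_equal(m1.sigma, m2.sigma)

    def test_misaligned_inputs_rejected(self, rng):
        ang = JointAngleTrajectory(theta=np.zeros((4, 50)), rate=100.0)
        with pytest.raises(InvalidInputError):
            ma.train_mixture(rng.standard_normal((40, 9)), ang)


class TestVelocityProxy:
    def test_recovers_linear_encoding(self, rng):
        femg = np.abs(rng.standard_normal((1000, 9)))
        ssv = 3.0 * femg[:, 4] + 0.2
        proxy = ma.fit_velocity_proxy(femg, ssv)
        out = ma.apply_velocity_proxy(proxy, femg)
        assert np.corrcoef(out, ssv)[0, 1] > 0.99

    def test_zero_emg_gives_clipped_bias(self):
        proxy = ma.VelocityProxy(w=np.ones(9), b=-2.0)
        out = ma.apply_velocity_proxy(proxy, np.zeros((10, 9)))
        np.testing.assert_allclose(out, 0.0)  # max(bias, 0)

    def test_output_never_negative(self, rng):
        femg = rng.standard_normal((500, 9))
        proxy = ma.fit_velocity_proxy(femg, rng.standard_normal(500))
        assert np.all(ma.apply_velocity_proxy(proxy, femg) >= 0)

    def test_constant_emg_warns(self):
        with pytest.warns(RuntimeWarning, match="rank"):
            ma.fit_velocity_proxy(np.ones((100, 9)), np.ones(100))


class TestPredictAngles:
    def _trained(self):
        u, ang, feat, regime = generate_regime_switching_data(
            5, n_samples=2000, block_len=200
        )
        model = ma.train_mixture(
            u, ang, ma.TrainConfig(epochs=1200, seed=0), gate_feature=feat
        )
        proxy = ma.fit_velocity_proxy(u, feat)
        return u, ang, model, proxy

    def test_heldout_prediction_quality(self):
        """On noiseless-map data the decoder tracks each joint closely."""
        u, ang, model, proxy = self._trained()
        pred = ma.predict_angles(model, proxy, u, rate=100.0)
        for k in range(4):
            assert np.corrcoef(pred.theta[k], ang.theta[k])[0, 1] > 0.95

    def test_constant_emg_gives_constant_output(self):
        _, _, model, proxy = self._trained()
        pred = ma.predict_angles(model, proxy, np.full((50, 9), 0.3), rate=100.0)
        assert np.allclose(pred.theta, pred.theta[:, :1])

    def test_stateless_across_sample_order(self):
        u, _, model, proxy = self._trained()
        perm = np.random.default_rng(0).permutation(len(u))
        direct = ma.predict_angles(model, proxy, u[perm], rate=100.0)
        swapped = ma.predict_angles(model, proxy, u, rate=100.0)
        np.testing.assert_allclose(direct.theta, swapped.theta[:, perm])

    def test_untrained_model_rejected(self):
        _, _, model, proxy = self._trained()
        model.trained = False
        with pytest.raises(ModelStateError):
            ma.predict_angles(model, proxy, np.zeros((10, 9)), rate=100.0)


class TestMonolithicBaseline:
    def test_matched_hidden_size_counts_parameters(self):
        cfg = ma.TrainConfig(n_experts=2, n_hidden=20)
        H = ma.matched_hidden_size(9, cfg, 10)
        per_expert = 9 * 20 + 20 + 20 * 4 + 4
        total = 2 * per_expert + 4
        mono = H * (10 + 1) + 4 * H + 4
        assert abs(mono - total) <= 15  # within one hidden unit's worth
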