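import numpy as np
import pytest

from cortexlimb import source_inverse as si
from cortexlimb.exceptions import (
    EstimationError,
    InvalidInputError,
    InvalidPriorError,
    InvalidRoiError,
)


def _simulate(seed, M=32, N=200, T=300, n_active=3, snr=10.0, active_var=1e-2):
    """Sparse-source forward simulation with known support."""
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((M, N)) / np.sqrt(M)
    var = np.full(N, active_var / 100.0)
    active = rng.choice(N, n_active, replace=False)
    var[active] = active_var
    J = rng.standard_normal((N, T)) * np.sqrt(var)[:, None]
    sig = G @ J
    noise_var = float(np.mean(sig**2) / snr)
    E = sig + rng.standard_normal((M, T)) * np.sqrt(noise_var)
    return G, J, E, active, noise_var


class TestFmriPrior:
    def test_zero_activation_keeps_baseline(self):
        p = si.prior_variance_from_fmri(si.FMRIPrior(np.zeros(5)), vbase=2.0)
        np.testing.assert_allclose(p.v0, 2.0)

    def test_full_activation_magnifies_by_m0(self):
        p = si.prior_variance_from_fmri(si.FMRIPrior(np.ones(3)), vbase=2.0, m0=100)
        np.testing.assert_allclose(p.v0, 200.0)

    def test_half_activation(self):
        p = si.prior_variance_from_fmri(
            si.FMRIPrior(np.array([0.5])), vbase=1.0, m0=100
        )
        assert np.isclose(p.v0[0], 25.75)

    def test_out_of_range_tvalues_rejected(self):
        with pytest.raises(InvalidPriorError):
            si.FMRIPrior(np.array([1.2]))

    def test_artifact_columns_get_magnified_variance(self):
        p = si.prior_variance_from_fmri(
            si.FMRIPrior(np.zeros(4)), vbase=1.0, m0=100, n_artifact=2
        )
        assert p.v0.shape == (6,)
        np.testing.assert_allclose(p.v0[-2:], 100.0)


class TestBaselineVariance:
    def test_recovers_known_uniform_variance(self):
        rng = np.random.default_rng(1)
        M, N, T = 16, 64, 2000
        G = rng.standard_normal((M, N)) / np.sqrt(M)
        vstar = 2.5
        J = rng.standard_normal((N, T)) * np.sqrt(vstar)
        sig = G @ J
        E = sig + rng.standard_normal((M, T)) * np.sqrt(np.mean(sig**2) / 100)
        est = si.estimate_baseline_variance(E, G)
        assert abs(est.vbase - vstar) / vstar < 0.2

    def test_quadratic_scale_equivariance(self, rng):
        G = rng.standard_normal((8, 32))
        E = rng.standard_normal((8, 500))
        a = si.estimate_baseline_variance(E, G)
        b = si.estimate_baseline_variance(3.0 * E, G)
        assert np.isclose(b.vbase, 9.0 * a.vbase, rtol=1e-3)
        assert np.isclose(b.noise_variance, 9.0 * a.noise_variance, rtol=1e-3)

    def test_pure_noise_yields_small_vbase(self):
        rng = np.random.default_rng(2)
        M, T = 16, 2000
        Q, _ = np.linalg.qr(rng.standard_normal((M, M)))
        noise_only = si.estimate_baseline_variance(
            rng.standard_normal((M, T)), Q
        )
        G = rng.standard_normal((M, 64)) / np.sqrt(M)
        J = rng.standard_normal((64, T))
        with_sources = si.estimate_baseline_variance(
            G @ J + 0.1 * rng.standard_normal((M, T)), G
        )
        assert noise_only.vbase < 0.05 * with_sources.vbase

    def test_empty_baseline_rejected(self):
        with pytest.raises(EstimationError):
            si.estimate_baseline_variance(np.zeros((4, 0)), np.eye(4))


class TestVBEstimate:
    def test_recovers_sparse_support(self):
        G, J, E, active, nv = _simulate(seed=0)
        prior = si.VariancePrior(v0=np.full(200, 1e-3), vbase=1e-3)
        state = si.vb_estimate(E, G, prior, noise_var=nv)
        top3 = np.argsort(state.alpha_inv)[-3:]
        assert set(top3) == set(active)

    def test_free_energy_monotone(self):
        G, J, E, active, nv = _simulate(seed=3)
        prior = si.VariancePrior(v0=np.full(200, 1e-3), vbase=1e-3)
        state = si.vb_estimate(E, G, prior, noise_var=nv)
        tr = state.free_energy_trace
        diffs = np.diff(tr)
        assert np.all(diffs >= -1e-9 * np.abs(tr[:-1]))
        assert state.converged

    def test_infinite_confidence_pins_posterior_to_prior(self):
        G, J, E, active, nv = _simulate(seed=1)
        prior = si.VariancePrior(v0=np.full(200, 1e-3), vbase=1e-3, r0=1e12)
        state = si.vb_estimate(E, G, prior, noise_var=nv, max_iter=50)
        v0_rel = 1e-3 / nv
        np.testing.assert_allclose(state.alpha_inv, v0_rel, rtol=1e-6)

    def test_nonconvergence_warns_and_returns_last_iterate(self):
        G, J, E, active, nv = _simulate(seed=2)
        prior = si.VariancePrior(v0=np.full(200, 1e-3), vbase=1e-3)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            state = si.vb_estimate(E, G, prior, noise_var=nv, max_iter=3)
        assert not state.converged and state.iterations == 3

    def test_dimension_mismatch_rejected(self):
        prior = si.VariancePrior(v0=np.ones(5), vbase=1.0)
        with pytest.raises(InvalidInputError):
            si.vb_estimate(np.zeros((4, 10)), np.zeros((3, 5)) + 1.0, prior)


class TestInverseFilter:
    def test_scalar_case(self):
        g, beta = 2.0, 4.0
        L = si.build_inverse_filter(np.ones(1), np.array([[g]]), beta=beta).L
        assert np.isclose(L[0, 0], g / (g**2 + 1 / beta))

    def test_matches_tikhonov_oracle(self, rng):
        """Uniform variance reduces the filter to a Tikhonov pseudo-inverse."""
        for _ in range(10):
            G = rng.standard_normal((16, 64))
            lam = float(rng.uniform(0.01, 10))
            L = si.build_inverse_filter(np.ones(64), G, beta=1 / lam).L
            oracle = G.T @ np.linalg.inv(G @ G.T + lam * np.eye(16))
            assert (
                np.linalg.norm(L - oracle) / np.linalg.norm(oracle) < 1e-6
            )

    def test_noiseless_limit_is_minimum_norm(self, rng):
        G = rng.standard_normal((8, 32))
        L = si.build_inverse_filter(np.ones(32), G, beta=1e12).L
        pinv = np.linalg.pinv(G)
        J0 = pinv @ rng.standard_normal(8)  # in the row space of G
        np.testing.assert_allclose(L @ (G @ J0), J0, atol=1e-6)

    def test_algebraic_identity(self, rng):
        """L (G S G' + beta^-1 I) = S G' for random SPD inputs."""
        G = rng.standard_normal((12, 40))
        var = rng.uniform(0.1, 5.0, 40)
        beta = 3.7
        L = si.build_inverse_filter(var, G, beta=beta).L
        K = G @ (G * var).T + (1 / beta) * np.eye(12)
        np.testing.assert_allclose(L @ K, (G * var).T, atol=1e-8)


class TestApplyInverse:
    def test_zero_input_zero_output(self):
        L = si.InverseFilter(L=np.ones((5, 3)))
        out = si.apply_inverse(L, np.zeros((3, 10)))
        assert np.allclose(out.J, 0)

    def test_linearity(self, rng):
        L = si.InverseFilter(L=rng.standard_normal((5, 3)))
        E1, E2 = rng.standard_normal((2, 3, 20))
        lhs = si.apply_inverse(L, 2.0 * E1 + 3.0 * E2).J
        rhs = 2.0 * si.apply_inverse(L, E1).J + 3.0 * si.apply_inverse(L, E2).J
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_high_snr_reconstruction_correlates(self):
        G, J, E, active, nv = _simulate(seed=5, snr=100.0, T=500)
        prior = si.VariancePrior(v0=np.full(200, 1e-3), vbase=1e-3)
        state = si.vb_estimate(E, G, prior, noise_var=nv)
        L = si.build_inverse_filter(state, G)
        Jhat = si.apply_inverse(L, E).J
        for v in active:
            cc = np.corrcoef(Jhat[v], J[v])[0, 1]
            assert cc > 0.9

    def test_shape_mismatch_rejected(self):
        L = si.InverseFilter(L=np.ones((5, 3)))
        with pytest.raises(InvalidInputError):
            si.apply_inverse(L, np.zeros((4, 10)))


class TestSelectRoi:
    def _lf(self):
        return si.LeadField(
            G=np.ones((4, 12)),
            n_cortex=10,
            roi_m1=np.arange(2, 5),
            artifact_idx=np.array([10, 11]),
        )

    def test_full_cortex_identity(self):
        est = si.SourceEstimate(J=np.arange(120.0).reshape(12, 10), rate=256.0)
        out = si.select_roi(est, roi=np.arange(10), lead_field=self._lf())
        np.testing.assert_array_equal(out.J, est.J[:10])

    def test_default_roi_is_m1(self):
        est = si.SourceEstimate(J=np.arange(120.0).reshape(12, 10), rate=256.0)
        out = si.select_roi(est, lead_field=self._lf())
        assert out.J.shape[0] == 3
        np.testing.assert_array_equal(out.indices, [2, 3, 4])

    def test_artifact_index_rejected(self):
        est = si.SourceEstimate(J=np.zeros((12, 10)), rate=256.0)
        with pytest.raises(InvalidRoiError):
            si.select_roi(est, roi=np.array([1, 10]), lead_field=self._lf())

    def test_out_of_range_rejected(self):
        est = si.SourceEstimate(J=np.zeros((12, 10)), rate=256.0)
        with pytest.raises(InvalidRoiError):
            si.select_roi(est, roi=np.array([55]), lead_field=self._lf())


class TestArtifactAugmentation:
    def test_modeling_artifacts_reduces_reconstruction_error(self):
        """Including artifact columns in G beats ignoring strong artifacts."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            M, N, T, n_art = 24, 100, 400, 3
            G = rng.standard_normal((M, N)) / np.sqrt(M)
            G_art = 2.0 * rng.standard_normal((M, n_art)) / np.sqrt(M)
            active = rng.choice(N, 4, replace=False)
            var = np.full(N, 1e-4)
            var[active] = 1.0
            J = rng.standard_normal((N, T)) * np.sqrt(var)[:, None]
            t = np.arange(T) / 256
            A = np.stack(
                [3 * np.sin(2 * np.pi * 1.2 * t + p)
                 for p in rng.uniform(0, 6, n_art)]
            )
            sig = G @ J
            nv = np.mean(sig**2) / 10
            E = sig + G_art @ A + rng.standard_normal((M, T)) * np.sqrt(nv)

            Gaug = np.concatenate([G, G_art], axis=1)
            p_aug = si.VariancePrior(
                v0=np.concatenate([np.full(N, 1e-2), np.full(n_art, 10.0)]),
                vbase=1e-2,
            )
            st = si.vb_estimate(E, Gaug, p_aug, noise_var=nv, max_iter=200)
            J_aug = (si.build_inverse_filter(st, Gaug).L @ E)[:N]

            p_no = si.VariancePrior(v0=np.full(N, 1e-2), vbase=1e-2)
            st2 = si.vb_estimate(E, G, p_no, noise_var=nv, max_iter=200)
            J_no = si.build_inverse_filter(st2, G).L @ E

            err_aug = np.linalg.norm(J_aug[active] - J[active])
            err_no = np.linalg.norm(J_no[active] - J[active])
            wins += err_aug < err_no
        assert wins >= 4
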