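"""Reconstruction operators, likelihood and priors of the four families."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from primsel.bss_models import (HyperParams, ModelFamily, ModelSpec,
                                ParameterSet, SignalMatrix, ica_log_normalizer,
                                log_cosh, log_likelihood, log_prior,
                                reconstruct_delayed, reconstruct_instantaneous,
                                shift_source)
from primsel.gp_prior import kernel_matrix


class TestReconstructInstantaneous:
    @pytest.mark.parametrize("W, S, expected", [
        ([[1.0]], [[2.0, 3.0]], [[2.0, 3.0]]),
        ([[0.0, 0.0]], [[1.0, 2.0], [3.0, 4.0]], [[0.0, 0.0]]),
        ([[1.0, 1.0]], [[1.0, 0.0], [0.0, 1.0]], [[1.0, 1.0]]),
    ])
    def test_known_products(self, W, S, expected):
        np.testing.assert_allclose(reconstruct_instantaneous(W, S), expected)

    def test_shape_mismatch_names_dimensions(self):
        with pytest.raises(ValueError, match="sources"):
            reconstruct_instantaneous(np.ones((2, 3)), np.ones((2, 5)))


class TestShiftSource:
    def test_zero_shift_is_identity(self, rng):
        s = rng.standard_normal(16)
        np.testing.assert_allclose(shift_source(s, 0.0), s, atol=1e-12)

    @given(st.integers(min_value=0, max_value=15))
    @settings(max_examples=16, deadline=None)
    def test_integer_shift_is_circular(self, k):
        s = np.random.default_rng(7).standard_normal(16)
        np.testing.assert_allclose(shift_source(s, k), np.roll(s, k), atol=1e-10)

    def test_fractional_shift_matches_analytic_sinusoid(self):
        T = 20
        t = np.arange(T)
        s = np.sin(2 * np.pi * 2 * t / T)
        shifted = shift_source(s, 0.5)
        expected = np.sin(2 * np.pi * 2 * (t - 0.5) / T)
        np.testing.assert_allclose(shifted, expected, atol=1e-6)

    def test_out_of_range_delay_rejected(self):
        with pytest.raises(ValueError, match="delay"):
            shift_source(np.ones(8), 8.0)
        with pytest.raises(ValueError, match="delay"):
            shift_source(np.ones(8), -0.5)


class TestReconstructDelayed:
    def test_zero_delays_reduce_to_instantaneous(self, rng):
        W = rng.standard_normal((3, 2))
        S = rng.standard_normal((2, 12))
        np.testing.assert_allclose(
            reconstruct_delayed(W, S, np.zeros((3, 2))),
            reconstruct_instantaneous(W, S), atol=1e-10)

    def test_single_source_integer_delay_is_circular_shift(self, rng):
        S = rng.standard_normal((1, 10))
        out = reconstruct_delayed([[1.0]], S, [[3.0]])
        np.testing.assert_allclose(out[0], np.roll(S[0], 3), atol=1e-10)

    def test_matches_dense_oversampled_shift_oracle(self, rng):
        # oracle: band-limited interpolation via zero-padded FFT upsampling
        T, up = 16, 100
        s = rng.standard_normal(T)
        F = np.fft.rfft(s)
        F[-1] *= 0.5  # split the Nyquist bin symmetrically when upsampling
        dense = np.fft.irfft(F, n=T * up) * up       # s on a 100x finer grid
        tau = 2.37
        W = np.array([[1.7]])
        out = reconstruct_delayed(W, s[None, :], [[tau]])
        idx = (np.arange(T) * up - int(round(tau * up))) % (T * up)
        expected = 1.7 * dense[idx]
        np.testing.assert_allclose(out[0], expected, atol=1e-5)


class TestLogLikelihood:
    def test_perfect_fit_single_point(self):
        X = SignalMatrix([[0.0, 0.0]], fs=1.0)
        val = log_likelihood(X, np.zeros((1, 2)), 1.0)
        assert val == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_known_residual(self):
        # residual norm^2 = 2 over two points with unit noise
        val = log_likelihood(np.array([[1.0, -1.0]]), np.zeros((1, 2)), 1.0)
        assert val == pytest.approx(-1.0 - np.log(2 * np.pi), abs=1e-12)

    def test_equals_sum_of_normal_logpdfs(self, rng):
        X = rng.standard_normal((3, 7))
        Xh = rng.standard_normal((3, 7))
        sn = 0.37
        expected = norm.logpdf(X, loc=Xh, scale=sn).sum()
        assert log_likelihood(X, Xh, sn) == pytest.approx(expected, rel=1e-12)

    def test_maximized_at_closed_form_sigma(self, rng):
        X = rng.standard_normal((4, 9))
        Xh = rng.standard_normal((4, 9))
        s_star = np.sqrt(np.mean((X - Xh) ** 2))
        best = log_likelihood(X, Xh, s_star)
        for s in (0.5 * s_star, 2.0 * s_star):
            assert log_likelihood(X, Xh, s) < best

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.ones((1, 2)), np.ones((1, 2)), 0.0)


class TestIcaLogNormalizer:
    def test_gaussian_limit(self):
        for sigma in (0.5, 1.0, 2.5):
            assert ica_log_normalizer(0.3, sigma, 0.0) == pytest.approx(
                0.5 * np.log(2 * np.pi * sigma ** 2), rel=1e-10)

    def test_translation_invariance(self):
        a = ica_log_normalizer(0.0, 1.2, 0.7)
        b = ica_log_normalizer(5.0, 1.2, 0.7)
        assert a == pytest.approx(b, rel=1e-10)

    def test_matches_importance_sampling(self):
        # MC oracle: Z = sqrt(2 pi s^2) E_{N(0,s^2)}[exp(lam G(u))]
        mu, sigma, lam = 0.0, 1.0, 0.5
        rng = np.random.default_rng(99)
        u = rng.normal(0.0, sigma, size=10 ** 6)
        w = np.exp(lam * log_cosh(u))
        est = np.log(np.mean(w)) + 0.5 * np.log(2 * np.pi * sigma ** 2)
        se = np.std(w) / (np.mean(w) * np.sqrt(u.size))
        assert abs(ica_log_normalizer(mu, sigma, lam) - est) < 3 * se

    def test_normalized_density_integrates_to_one(self):
        mu, sigma, lam = 0.4, 0.8, -0.9
        log_z = ica_log_normalizer(mu, sigma, lam)
        val, _ = quad(lambda s: np.exp(-0.5 * ((s - mu) / sigma) ** 2
                                       + lam * log_cosh(s - mu) - log_z),
                      mu - 15 * sigma, mu + 15 * sigma, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)


class TestLogPrior:
    def test_ppca_mode_is_pure_normalizer(self):
        J, I, T = 3, 2, 5
        phi = HyperParams(sigma_n=1.0, sigma_w=0.7, mu=0.4, sigma=1.3)
        theta = ParameterSet(np.zeros((J, I)), np.full((I, T), phi.mu))
        spec = ModelSpec("ppca", I)
        expected = (-0.5 * I * T * np.log(2 * np.pi * phi.sigma ** 2)
                    - 0.5 * J * I * np.log(2 * np.pi * phi.sigma_w ** 2))
        assert log_prior(theta, phi, spec) == pytest.approx(expected, rel=1e-12)

    def test_amm_zero_delays_adds_exponential_density_at_zero(self, rng):
        J, I, T = 3, 2, 12
        phi = HyperParams(sigma_n=1.0, sigma_w=1.0, mu=0.0, sigma=1.0,
                          gamma=7.0, f0=6.0)
        W = rng.standard_normal((J, I))
        S = rng.standard_normal((I, T))
        kern = kernel_matrix(T, 100.0, 6.0, phi.sigma ** 2)
        lp_sim = log_prior(ParameterSet(W, S), phi, ModelSpec("sim", I, 6.0), kern)
        lp_amm = log_prior(ParameterSet(W, S, np.zeros((J, I))), phi,
                           ModelSpec("amm", I, 6.0), kern)
        assert lp_amm - lp_sim == pytest.approx(J * I * np.log(1 / phi.gamma),
                                                rel=1e-10)

    def test_ica_lambda_zero_equals_ppca(self, rng):
        J, I, T = 2, 2, 8
        phi = HyperParams(sigma_n=1.0, sigma_w=1.5, mu=0.2, sigma=0.9, lam=0.0)
        theta = ParameterSet(rng.standard_normal((J, I)), rng.standard_normal((I, T)))
        assert log_prior(theta, phi, ModelSpec("ica", I)) == pytest.approx(
            log_prior(theta, phi, ModelSpec("ppca", I)), rel=1e-10)

    def test_kernel_bundle_requirement_enforced(self, rng):
        theta = ParameterSet(rng.standard_normal((2, 1)), rng.standard_normal((1, 6)))
        phi = HyperParams(sigma_n=1.0, sigma_w=1.0)
        kern = kernel_matrix(6, 100.0, 5.0, 1.0)
        with pytest.raises(ValueError, match="kernel"):
            log_prior(theta, phi, ModelSpec("sim", 1, 5.0), None)
        with pytest.raises(ValueError, match="kernel"):
            log_prior(theta, phi, ModelSpec("ppca", 1), kern)

    def test_finite_on_interior(self, rng):
        theta = ParameterSet(rng.standard_normal((3, 2)),
                             rng.standard_normal((2, 10)),
                             rng.uniform(0, 9, (3, 2)))
        phi = HyperParams(sigma_n=0.5, sigma_w=2.0, mu=0.0, sigma=1.1,
                          gamma=20.0, f0=8.0)
        kern = kernel_matrix(10, 100.0, 8.0, phi.sigma ** 2)
        assert np.isfinite(log_prior(theta, phi, ModelSpec("amm", 2, 8.0), kern))


class TestValidation:
    def test_signal_matrix_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            SignalMatrix(np.array([[1.0, np.nan]]), fs=100.0)

    def test_signal_matrix_needs_two_time_points(self):
        with pytest.raises(ValueError):
            SignalMatrix(np.ones((2, 1)), fs=100.0)

    def test_parameter_set_shape_checks(self):
        with pytest.raises(ValueError):
            ParameterSet(np.ones((2, 2)), np.ones((3, 5)))
        with pytest.raises(ValueError):
            ParameterSet(np.ones((2, 1)), np.ones((1, 5)), np.full((2, 1), 5.0))

    def test_model_spec_rejects_finite_cutoff_for_ppca(self):
        with pytest.raises(ValueError):
            ModelSpec(ModelFamily.PPCA, 2, 5.0)
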