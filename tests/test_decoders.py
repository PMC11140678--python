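"""Ridge decoders: lagged design construction, dual/primal equivalence,
leave-one-stimulus-out penalty selection, and logistic phoneme models."""

import numpy as np
import pytest

from cortrack.decoders import (
    DEFAULT_PENALTY_GRID,
    build_lagged_design,
    fit_convolution,
    fit_logistic_phonemes,
    fit_ridge_static,
    lag_matrix,
    lag_window_ms,
    loo_lambda_select,
    predict_phonemes,
    predict_static,
    predict_time_varying,
    ridge_dual,
    ridge_primal,
)


def brute_force_lag_matrix(response, lags_ms, rate, n_frames, onset=0):
    """Element-wise reference constructor: row t is r(t + tau, x)."""
    n_sensors, n_times = response.shape
    taus = np.round(np.asarray(lags_ms) * rate / 1000.0).astype(int)
    out = np.zeros((n_frames, len(taus) * n_sensors))
    for t in range(n_frames):
        col = 0
        for tau in taus:
            for x in range(n_sensors):
                i = onset + t + tau
                out[t, col] = response[x, i] if 0 <= i < n_times else 0.0
                col += 1
    return out


class TestLaggedDesign:
    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        resp = rng.standard_normal((3, 40))
        got = lag_matrix(resp, [10, 20, 50], 100.0, 12, onset=5)
        want = brute_force_lag_matrix(resp, [10, 20, 50], 100.0, 12, onset=5)
        np.testing.assert_array_equal(got, want)

    def test_single_sensor_index_arithmetic(self):
        resp = np.arange(5.0)[None, :]  # r(t) = t
        got = lag_matrix(resp, [10, 20], 100.0, 5)
        # row at t=3 holds the response at t+1 and t+2 samples
        np.testing.assert_array_equal(got[3], [4.0, 0.0])
        np.testing.assert_array_equal(got[2], [3.0, 4.0])

    def test_zero_lag_window_is_identity(self):
        rng = np.random.default_rng(1)
        resp = rng.standard_normal((4, 6))
        got = lag_matrix(resp, [0], 100.0, 6)
        np.testing.assert_array_equal(got, resp.T)

    def test_overview_window_has_41_lags(self):
        lags = lag_window_ms(20, 420, rate=100.0)
        assert len(lags) == 41

    def test_lag_validation(self):
        with pytest.raises(ValueError):
            lag_window_ms(100, 50)
        with pytest.raises(ValueError):
            lag_matrix(np.zeros((1, 10)), [-10], 100.0, 5)

    def test_build_stacks_per_stimulus(self):
        rng = np.random.default_rng(2)
        resp = [rng.standard_normal((2, 30)) for _ in range(3)]
        d = build_lagged_design(resp, [10, 20], 100.0, [5, 7, 4], onset=3)
        assert d.matrix.shape == (16, 4)
        assert list(np.bincount(d.row_stimulus)) == [5, 7, 4]
        np.testing.assert_array_equal(
            d.matrix[:5], brute_force_lag_matrix(resp[0], [10, 20], 100.0, 5, 3)
        )


class TestRidge:
    @pytest.mark.parametrize("lam", [1e-3, 1.0, 1e4])
    def test_dual_equals_primal(self, lam):
        rng = np.random.default_rng(3)
        R = rng.standard_normal((8, 5))
        S = rng.standard_normal((8, 2))
        np.testing.assert_allclose(
            ridge_dual(R, S, lam), ridge_primal(R, S, lam), atol=1e-8
        )

    def test_interpolation_limit(self):
        rng = np.random.default_rng(4)
        R = rng.standard_normal((6, 6))
        S = rng.standard_normal((6, 1))
        w = ridge_dual(R, S, 1e-12)
        assert np.max(np.abs(R @ w - S)) < 1e-6

    def test_recovers_true_weights_noise_free(self):
        rng = np.random.default_rng(5)
        R = rng.standard_normal((60, 10))  # full column rank
        g0 = rng.standard_normal((10, 1))
        w = ridge_primal(R, R @ g0, 1e-10)
        np.testing.assert_allclose(w, g0, atol=1e-6)

    def test_loo_matches_explicit_refit(self):
        rng = np.random.default_rng(6)
        n_stim, T, D = 6, 4, 5
        R = rng.standard_normal((n_stim * T, D))
        S = rng.standard_normal((n_stim * T, 1))
        owner = np.repeat(np.arange(n_stim), T)
        grid = (0.1, 1.0, 10.0)
        _, errors = loo_lambda_select(R, S, owner, grid)
        for gi, lam in enumerate(grid):
            err = 0.0
            for n in range(n_stim):
                tr = owner != n
                w = ridge_primal(R[tr], S[tr], lam)
                err += float(((R[~tr] @ w - S[~tr]) ** 2).sum())
            assert errors[gi] == pytest.approx(err, rel=1e-8)

    def test_loo_dual_path_agrees_with_primal_path(self):
        rng = np.random.default_rng(7)
        R = rng.standard_normal((12, 4))
        S = rng.standard_normal((12, 1))
        owner = np.repeat(np.arange(4), 3)
        grid = (0.1, 1.0, 10.0)
        _, e_primal = loo_lambda_select(R, S, owner, grid, solver="primal")
        _, e_dual = loo_lambda_select(R, S, owner, grid, solver="dual")
        np.testing.assert_allclose(e_primal, e_dual, rtol=1e-8)

    def test_grid_validation(self):
        R = np.eye(3)
        with pytest.raises(ValueError):
            loo_lambda_select(R, R[:, :1], np.arange(3), grid=(1.0, 0.5, 2.0))


class TestConvolutionModel:
    def _design(self, seed=8, n_stim=5, n_sensors=3, T=20):
        rng = np.random.default_rng(seed)
        resp = [rng.standard_normal((n_sensors, T + 10)) for _ in range(n_stim)]
        d = build_lagged_design(resp, [10, 20, 30], 100.0, [T] * n_stim)
        return rng, d

    def test_forward_recovery(self):
        rng, d = self._design()
        g0 = rng.standard_normal((d.matrix.shape[1], 1))
        model = fit_convolution(d, d.matrix @ g0, grid=(1e-8, 1e-6, 1e-4))
        np.testing.assert_allclose(model.weights, g0, atol=1e-4)

    def test_channel_independence(self):
        rng, d = self._design(seed=9)
        S = rng.standard_normal((d.matrix.shape[0], 3))
        m = fit_convolution(d, S, grid=(0.1, 1.0, 10.0))
        perm = [2, 0, 1]
        m_perm = fit_convolution(d, S[:, perm], grid=(0.1, 1.0, 10.0))
        np.testing.assert_allclose(m_perm.weights, m.weights[:, perm], atol=1e-10)
        np.testing.assert_allclose(m_perm.lambdas, m.lambdas[perm])

    def test_prediction_linearity_and_zero(self):
        rng, d = self._design(seed=10)
        S = rng.standard_normal((d.matrix.shape[0], 1))
        model = fit_convolution(d, S, grid=(0.1, 1.0, 10.0))
        resp = rng.standard_normal((3, 30))
        p1 = predict_time_varying(model, resp, 20)
        p2 = predict_time_varying(model, 2.5 * resp, 20)
        np.testing.assert_allclose(p2, 2.5 * p1, atol=1e-10)
        assert np.all(predict_time_varying(model, np.zeros((3, 30)), 20) == 0)
        with pytest.raises(ValueError, match="sensor"):
            predict_time_varying(model, np.zeros((5, 30)), 20)


class TestStaticRidge:
    def test_dual_equals_primal_small(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((8, 5))
        S = rng.standard_normal((8, 1))
        m = fit_ridge_static(X, S, lambdas=[2.0])
        np.testing.assert_allclose(
            m.weights, ridge_primal(X, S, 2.0), atol=1e-8
        )

    def test_linear_target_predicts_held_out(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((13, 6))  # overdetermined: w identifiable
        w_true = rng.standard_normal((6, 1))
        S = X @ w_true
        m = fit_ridge_static(X[:12], S[:12], grid=(1e-8, 1e-6, 1e-4))
        pred = predict_static(m, X[12:])
        np.testing.assert_allclose(pred, S[12:], atol=1e-3)

    def test_constant_feature_gives_zero_weights(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((8, 6))
        S = np.zeros((8, 1))  # standardized constant feature
        m = fit_ridge_static(X, S, grid=DEFAULT_PENALTY_GRID)
        assert np.max(np.abs(m.weights)) < 1e-10


class TestLogisticPhonemes:
    def _separable(self, seed=14):
        rng = np.random.default_rng(seed)
        n_stim, T = 4, 10
        resp = [rng.standard_normal((2, T + 5)) for _ in range(n_stim)]
        d = build_lagged_design(resp, [0], 100.0, [T] * n_stim)
        w_true = np.array([1.5, -2.0])
        y = np.where(d.matrix @ w_true > 0, 1.0, -1.0)
        return d, y

    def test_separable_data_fits_perfectly(self):
        d, y = self._separable()
        model = fit_logistic_phonemes(d, y[None, :], ["a"], alpha=1e-6, seed=0)
        w, b = model.coefs["a"]
        acc = np.mean(np.where(d.matrix @ w + b > 0, 1, -1) == y)
        assert acc == 1.0

    def test_single_class_phoneme_skipped(self):
        d, y = self._separable()
        Y = np.stack([y, -np.ones_like(y)])
        with pytest.warns(RuntimeWarning, match="single-class"):
            model = fit_logistic_phonemes(d, Y, ["a", "b"], seed=0)
        assert model.skipped == ["b"]
        act, prob = predict_phonemes(model, np.zeros((2, 10)), 5)
        assert np.all(prob[1] == 0.5) and np.all(act[1] == -1)

    def test_half_probability_is_inactive_strictly(self):
        d, y = self._separable()
        model = fit_logistic_phonemes(d, y[None, :], ["a"], seed=0)
        model.coefs["a"] = (np.zeros(2), 0.0)  # p = 0.5 everywhere
        act, prob = predict_phonemes(model, np.ones((2, 8)), 8)
        assert np.all(prob == 0.5) and np.all(act == -1)

    def test_sign_flip_flips_activity(self):
        d, y = self._separable()
        model = fit_logistic_phonemes(d, y[None, :], ["a"], alpha=1e-6, seed=0)
        rng = np.random.default_rng(15)
        resp = rng.standard_normal((2, 12))
        act, prob = predict_phonemes(model, resp, 10)
        w, b = model.coefs["a"]
        model.coefs["a"] = (-w, -b)
        act2, prob2 = predict_phonemes(model, resp, 10)
        flip = prob[0] != 0.5
        assert np.all(act2[0, flip] == -act[0, flip])
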