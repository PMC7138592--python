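"""Relevance vector regression: ridge limit, evidence monotonicity,
sparsity, prediction identities and voxel-space back-projection."""

import numpy as np
import pytest

from wmlpredict import (
    RelevanceVectorRegression,
    RVRState,
    Volume,
    backproject_weights,
    fit_rvr,
    predict_rvr,
)


def make_problem(rng, n=30, d=60, k_informative=4, noise=0.05):
    X = rng.normal(size=(n, d))
    w = np.zeros(d)
    w[rng.choice(d, k_informative, replace=False)] = rng.normal(
        size=k_informative
    )
    y = X @ w + noise * rng.normal(size=n)
    return X, y


class TestFitBasics:
    def test_constant_target_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="constant"):
            RelevanceVectorRegression().fit(X, np.ones(10))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            RelevanceVectorRegression().fit(rng.normal(size=(2, 4)),
                                            np.array([1.0, 2.0]))

    def test_nonfinite_rejected(self, rng):
        X = rng.normal(size=(5, 4))
        y = np.array([1.0, 2.0, np.nan, 0.0, 1.0])
        with pytest.raises(ValueError, match="finite"):
            RelevanceVectorRegression().fit(X, y)

    def test_fitted_attributes(self, rng):
        X, y = make_problem(rng)
        est = RelevanceVectorRegression().fit(X, y)
        assert est.sigma2_ > 0
        assert (est.alpha_ > 0).all()
        assert len(est.relevance_) <= X.shape[0]
        assert est.n_iter_ >= 1

    def test_sklearn_param_round_trip(self):
        est = RelevanceVectorRegression(tol=1e-4, max_iter=42)
        params = est.get_params()
        assert params["tol"] == 1e-4
        est2 = RelevanceVectorRegression().set_params(**params)
        assert est2.max_iter == 42


class TestRealizableTarget:
    def test_kernel_column_target_reproduced(self, rng):
        """A target equal to one kernel column is fit almost exactly."""
        X = rng.normal(size=(20, 30))
        K = X @ X.T
        y = K[:, 7].copy()
        est = RelevanceVectorRegression().fit(X, y)
        yhat = est.predict(X)
        rel_err = np.linalg.norm(y - yhat) / np.linalg.norm(y)
        assert rel_err < 1e-6


class TestRidgeLimit:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_frozen_hyperparams_match_ridge_closed_form(self, seed):
        """With alpha and sigma^2 frozen, the posterior mean is the ridge
        solution (Phi^T Phi + alpha sigma^2 I)^-1 Phi^T y."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 200))
        y = rng.normal(size=50)
        a, s2 = 0.5, 2.0
        est = RelevanceVectorRegression(
            alpha_init=a, sigma2_init=s2, bias_alpha=a,
            update_hyperparams=False, normalize_basis=False,
        ).fit(X, y)
        Phi = np.column_stack([np.ones(50), X @ X.T])
        mu_ridge = np.linalg.solve(
            Phi.T @ Phi + a * s2 * np.eye(51), Phi.T @ y
        )
        np.testing.assert_allclose(est.mu_, mu_ridge, rtol=1e-8, atol=1e-10)


class TestEvidenceAndSparsity:
    @pytest.mark.parametrize("seed", range(5))
    def test_log_marginal_likelihood_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        X, y = make_problem(rng, n=25, d=40)
        est = RelevanceVectorRegression().fit(X, y)
        diffs = np.diff(est.lml_path_)
        assert diffs.min() > -1e-6

    def test_pure_noise_prunes_heavily(self):
        """Targets independent of correlated (lesion-map-like) features:
        nearly all basis functions are pruned and the noise variance is
        estimated near var(y)."""
        # feature correlation is essential: a sample-space kernel model has
        # nothing to prune against an orthogonal basis
        rng = np.random.default_rng(99)
        n, d, r = 40, 500, 6
        X = rng.normal(size=(n, r)) @ rng.normal(size=(r, d)) \
            + 0.1 * rng.normal(size=(n, d))
        y = rng.normal(size=n)
        est = RelevanceVectorRegression().fit(X, y)
        assert len(est.relevance_) <= 0.10 * (n + 1)
        assert 0.5 * np.var(y) < est.sigma2_ < 2.0 * np.var(y)

    def test_signal_recovery_out_of_sample(self):
        """Sparse voxel signal carried by a correlated voxel block is
        predicted well out of sample."""
        rng = np.random.default_rng(7)
        n, d, nb = 120, 2000, 20
        Z = rng.normal(size=(n, nb))
        assign = rng.integers(0, nb, d)
        X = Z[:, assign] + 0.5 * rng.normal(size=(n, d))
        w = np.zeros(d)
        w[np.flatnonzero(assign == 3)[:5]] = 1.0
        y = X @ w + 0.5 * rng.normal(size=n)
        est = RelevanceVectorRegression().fit(X[:80], y[:80])
        r = np.corrcoef(y[80:], est.predict(X[80:]))[0, 1]
        assert r >= 0.5
        assert len(est.relevance_) < 80


class TestPredictionIdentities:
    def test_training_predictions_match_fit(self, rng):
        X, y = make_problem(rng)
        est = RelevanceVectorRegression().fit(X, y)
        Phi = np.column_stack([np.ones(X.shape[0]),
                               X @ est.X_rv_.T])
        np.testing.assert_allclose(est.predict(X), Phi @ est.mu_,
                                   rtol=1e-10, atol=1e-12)

    def test_zero_input_gives_bias(self, rng):
        X, y = make_problem(rng)
        est = RelevanceVectorRegression().fit(X, y)
        assert est.predict(np.zeros((1, X.shape[1])))[0] == pytest.approx(
            est.mu_[0]
        )

    def test_linearity_identity(self, rng):
        X, y = make_problem(rng)
        est = RelevanceVectorRegression().fit(X, y)
        x = rng.normal(size=(1, X.shape[1]))
        f0 = est.predict(np.zeros_like(x))[0]
        f1 = est.predict(x)[0]
        f2 = est.predict(2 * x)[0]
        assert f2 - f0 == pytest.approx(2 * (f1 - f0), rel=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = make_problem(rng)
        est = RelevanceVectorRegression().fit(X, y)
        with pytest.raises(ValueError, match="dimension"):
            est.predict(rng.normal(size=(3, X.shape[1] + 1)))


class TestBackProjection:
    def test_kernel_and_voxel_predictors_agree(self, rng):
        X, y = make_problem(rng, n=40, d=80)
        est = RelevanceVectorRegression().fit(X, y)
        w_vox = est.voxel_weights()
        Xnew = rng.normal(size=(20, 80))
        np.testing.assert_allclose(
            est.predict(Xnew), Xnew @ w_vox + est.mu_[0],
            rtol=1e-8, atol=1e-10,
        )

    def test_single_relevance_vector_map_equals_features(self):
        feats = np.arange(6, dtype=float).reshape(1, 6)
        state = RVRState(
            relevance_indices=np.array([0]),
            posterior_mean_weights=np.array([0.0, 1.0]),  # bias, mu=1
            alpha=np.array([1e-6, 1.0]),
            sigma2=1.0,
            kernel="linear",
            training_feature_refs=feats,
            converged=True,
            n_iterations=1,
        )
        mask = Volume(np.ones((1, 2, 3), dtype=np.uint8), (2, 2, 2))
        wmap = backproject_weights(state, mask)
        np.testing.assert_array_equal(wmap.weights.data.ravel(),
                                      feats.ravel())

    def test_empty_relevance_set_gives_zero_map_and_bias_predictor(self):
        state = RVRState(
            relevance_indices=np.array([], dtype=int),
            posterior_mean_weights=np.array([3.25]),
            alpha=np.array([1e-6]),
            sigma2=1.0,
            kernel="linear",
            training_feature_refs=np.empty((0, 6)),
            converged=True,
            n_iterations=1,
        )
        mask = Volume(np.ones((1, 2, 3), dtype=np.uint8), (2, 2, 2))
        wmap = backproject_weights(state, mask)
        assert (wmap.weights.data == 0).all()
        np.testing.assert_allclose(
            predict_rvr(state, np.random.default_rng(0).normal(size=(4, 6))),
            3.25,
        )

    def test_weight_map_zero_outside_mask(self, rng):
        X, y = make_problem(rng, n=15, d=10)
        state = fit_rvr(X, y)
        mask_data = np.zeros((2, 3, 4), dtype=np.uint8)
        mask_data.ravel()[:10] = 1  # 10 in-mask voxels = feature dim
        mask = Volume(mask_data, (2, 2, 2))
        wmap = backproject_weights(state, mask)
        assert (wmap.weights.data[mask_data == 0] == 0).all()

    def test_nonlinear_kernel_rejected(self, rng):
        X, y = make_problem(rng, n=10, d=5)
        est = RelevanceVectorRegression(kernel="precomputed").fit(X @ X.T, y)
        from wmlpredict.rvr import _state_from_estimator

        state = _state_from_estimator(est)
        mask = Volume(np.ones((1, 1, 5), dtype=np.uint8), (2, 2, 2))
        with pytest.raises(ValueError, match="linear"):
            backproject_weights(state, mask)


class TestPrecomputedKernel:
    def test_matches_linear_kernel_fit(self, rng):
        X, y = make_problem(rng)
        lin = RelevanceVectorRegression(kernel="linear").fit(X, y)
        pre = RelevanceVectorRegression(kernel="precomputed").fit(X @ X.T, y)
        np.testing.assert_array_equal(lin.relevance_, pre.relevance_)
        np.testing.assert_allclose(lin.mu_, pre.mu_, rtol=1e-10)
        Xnew = rng.normal(size=(6, X.shape[1]))
        np.testing.assert_allclose(
            lin.predict(Xnew), pre.predict(Xnew @ X.T), rtol=1e-10
        )

    def test_state_json_round_trip(self, tmp_path, rng):
        X, y = make_problem(rng, n=12, d=8)
        state = fit_rvr(X, y)
        path = tmp_path / "state.json"
        state.to_json(path)
        back = RVRState.from_json(path)
        np.testing.assert_array_equal(back.relevance_indices,
                                      state.relevance_indices)
        np.testing.assert_allclose(back.posterior_mean_weights,
                                   state.posterior_mean_weights)
        Xnew = rng.normal(size=(4, 8))
        np.testing.assert_allclose(predict_rvr(back, Xnew),
                                   predict_rvr(state, Xnew))
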