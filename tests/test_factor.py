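"""Alternating maximum-likelihood factor fitting."""

import numpy as np
import pytest
from sklearn.base import clone

from gzigpfa import (
    CountMatrix,
    GZIGPFA,
    LogPCA,
    ZigpParams,
    fit_factors,
    frobenius_loss,
    predicted_zero_matrix,
    relative_library_size,
    svd_init,
    zigp_total_zero_prob,
)
from gzigpfa.factor import _reidentify


class TestRelativeLibrarySize:
    def test_median_normalization(self):
        Y = np.zeros((3, 2), dtype=int)
        Y[0, 0], Y[1, 0], Y[2, 0] = 10, 20, 30
        np.testing.assert_allclose(relative_library_size(Y), [0.5, 1.0, 1.5])

    def test_identical_rows_give_unit_sizes(self):
        Y = np.tile([3, 4, 5], (4, 1))
        np.testing.assert_allclose(relative_library_size(Y), np.ones(4))

    def test_even_sample_count_uses_midpoint_median(self):
        Y = np.diag([4, 8, 8, 100]).astype(int)
        np.testing.assert_allclose(relative_library_size(Y), [0.5, 1.0, 1.0, 12.5])

    def test_zero_row_names_the_sample(self):
        cm = CountMatrix(np.array([[1, 2], [0, 0]]), sample_ids=["a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            relative_library_size(cm)


class TestSvdInit:
    def test_rank_one_toy(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([2.0, 1.0, 0.5])
        Y = np.rint(np.exp(np.outer(np.log1p(u), np.log1p(v)))).astype(int) + 1
        F0, L0 = svd_init(Y, 1, T=np.ones(3))
        Ytil = np.log(Y + 1.0)
        U, s, Vt = np.linalg.svd(Ytil)
        np.testing.assert_allclose(F0 @ L0.T, s[0] * np.outer(U[:, 0], Vt[0]), atol=1e-10)

    def test_truncation_error_is_tail_singular_norm(self, rng):
        Y = rng.integers(0, 50, size=(20, 10))
        K = 3
        F0, L0 = svd_init(Y, K, T=np.ones(20))
        Ytil = np.log(Y + 1.0)
        s = np.linalg.svd(Ytil, compute_uv=False)
        resid = np.linalg.norm(Ytil - F0 @ L0.T)
        assert resid == pytest.approx(np.sqrt((s[K:] ** 2).sum()), rel=1e-10)

    def test_rank_bound(self):
        with pytest.raises(ValueError):
            svd_init(np.ones((4, 3), dtype=int), 5)


def test_reidentification_preserves_product_and_orthogonalizes(rng):
    F = rng.normal(size=(40, 3))
    L = rng.normal(size=(15, 3))
    F2, L2 = _reidentify(F, L)
    assert np.linalg.norm(F2 @ L2.T - F @ L.T) < 1e-8
    np.testing.assert_allclose(F2.T @ F2, np.diag(np.diag(F2.T @ F2)), atol=1e-8)
    np.testing.assert_allclose(L2.T @ L2, np.eye(3), atol=1e-10)


class TestFit:
    @pytest.fixture(scope="class")
    def fitted(self, small_dataset):
        model = GZIGPFA(n_components=3, library_size="ones", tol=1e-5, max_iter=40)
        return model.fit(small_dataset.Y.Y)

    def test_loglik_trace_monotone_and_svd_invariant(self, fitted):
        tr = np.asarray(fitted.loglik_trace_)
        assert np.all(np.diff(tr) >= -1e-6 * np.abs(tr[:-1]))
        # entries 3k+2 and 3k+3 bracket the SVD re-identification step
        steps = tr[1:].reshape(-1, 3)
        np.testing.assert_allclose(steps[:, 1], steps[:, 2], rtol=1e-6)

    def test_recovers_rates_better_than_log_pca(self, fitted, small_dataset):
        ours = frobenius_loss(fitted.log_rate_, small_dataset.logLambda_true)
        baseline = frobenius_loss(
            LogPCA(n_components=3).fit(small_dataset.Y.Y).log_rate_,
            small_dataset.logLambda_true,
        )
        assert ours < baseline

    def test_factor_columns_are_orthogonal(self, fitted):
        FtF = fitted.F_.T @ fitted.F_
        np.testing.assert_allclose(FtF, np.diag(np.diag(FtF)), atol=1e-6)
        np.testing.assert_allclose(fitted.L_.T @ fitted.L_, np.eye(3), atol=1e-8)

    def test_predicted_zero_probability_matches_entrywise_oracle(self, fitted):
        P = fitted.predict_zero_proba()
        eta = fitted.log_rate_
        for i, j in [(0, 0), (3, 7), (59, 29), (17, 11)]:
            lam = np.exp(eta[i, j])
            phi = 1 / (1 + lam ** fitted.tau_)
            want = zigp_total_zero_prob(phi, fitted.T_[i] * lam, fitted.alpha_)
            assert P[i, j] == pytest.approx(want, rel=1e-9)
        assert np.all((P > 0) & (P < 1))

    def test_fit_is_deterministic(self, fitted, small_dataset):
        again = GZIGPFA(n_components=3, library_size="ones", tol=1e-5, max_iter=40).fit(
            small_dataset.Y.Y
        )
        np.testing.assert_array_equal(again.log_rate_, fitted.log_rate_)

    def test_transform_recovers_training_scores(self, fitted, small_dataset):
        F = fitted.transform(small_dataset.Y.Y)
        # same rotational frame (loadings fixed); scores should be close
        assert np.linalg.norm(F - fitted.F_) / np.linalg.norm(fitted.F_) < 0.05

    def test_global_parameter_recovery(self, scenario1_dataset):
        model = GZIGPFA(n_components=3, library_size="ones").fit(scenario1_dataset.Y.Y)
        assert model.alpha_ == pytest.approx(0.2, abs=0.05)
        assert model.tau_ == pytest.approx(scenario1_dataset.tau_used, abs=0.3)


class TestMaskedFit:
    def test_masked_entries_do_not_change_shape_and_loglik_uses_mask(self, small_dataset):
        rng = np.random.default_rng(0)
        mask = rng.random(small_dataset.Y.shape) > 0.1
        model = GZIGPFA(n_components=2, library_size="ones", max_iter=10)
        model.fit(small_dataset.Y.Y, mask=mask)
        assert model.F_.shape == (60, 2)
        assert np.isfinite(model.loglik_)


class TestEstimatorContract:
    def test_clone_and_params_roundtrip(self):
        model = GZIGPFA(n_components=4, tol=1e-5, library_size="ones")
        params = model.get_params()
        assert params["n_components"] == 4
        cloned = clone(model)
        assert cloned.get_params() == params

    def test_fit_transform_returns_scores(self, small_dataset):
        model = GZIGPFA(n_components=2, library_size="ones", max_iter=5)
        F = model.fit_transform(small_dataset.Y.Y)
        np.testing.assert_array_equal(F, model.F_)

    def test_rejects_all_zero_matrix(self):
        with pytest.raises(ValueError):
            GZIGPFA(n_components=1).fit(np.zeros((5, 4), dtype=int))

    def test_rejects_excessive_rank(self, small_dataset):
        with pytest.raises(ValueError):
            GZIGPFA(n_components=40).fit(small_dataset.Y.Y)


def test_functional_wrapper_returns_factor_fit(small_dataset):
    fit = fit_factors(small_dataset.Y.Y, 2, library_size="ones", max_iter=6, tol=1e-3)
    assert fit.F.shape == (60, 2)
    assert fit.L.shape == (30, 2)
    assert isinstance(fit.params, ZigpParams)
    P = predicted_zero_matrix(fit)
    assert P.shape == (60, 30)
    assert np.all((P > 0) & (P < 1))
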