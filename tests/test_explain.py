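import numpy as np
import pytest

from stentrisk import (
    feature_overlap,
    interaction_summary,
    lasso_logistic_path,
    shap_importance,
    shapley_values,
)


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(0)
    n = 250
    X = rng.normal(size=(n, 8))
    eta = 1.4 * X[:, 0] - 1.0 * X[:, 1] + 0.6 * X[:, 2]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


@pytest.fixture(scope="module")
def path(xy):
    X, y = xy
    return lasso_logistic_path(X, y, n_lambdas=30, cv_folds=3, seed=0)


class TestLassoPath:
    def test_all_coefficients_zero_at_lambda_max(self, path):
        assert np.abs(path.coefs[:, 0]).max() < 1e-8

    def test_kkt_subgradient_optimality_along_path(self, xy, path):
        X, y = xy
        n = len(y)
        for i in range(0, len(path.lambdas), 7):
            lam = path.lambdas[i]
            w, b = path.coefs[:, i], path.intercepts[i]
            p = 1 / (1 + np.exp(-(X @ w + b)))
            g = X.T @ (p - y) / n
            zero = np.abs(w) < 1e-10
            if zero.any():
                assert np.abs(g[zero]).max() <= lam + 1e-6
            if (~zero).any():
                assert np.abs(g[~zero] + lam * np.sign(w[~zero])).max() < 1e-5

    def test_noise_column_zeroes_before_signal(self):
        rng = np.random.default_rng(3)
        n = 400
        X = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        eta = 2.0 * X[:, 0]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        path = lasso_logistic_path(X, y, n_lambdas=25, cv_folds=3, seed=0)
        active_signal = np.abs(path.coefs[0]) > 1e-10
        active_noise = np.abs(path.coefs[1]) > 1e-10
        # signal enters the path no later than the noise column
        first = lambda a: np.argmax(a) if a.any() else len(a)
        assert first(active_signal) <= first(active_noise)

    def test_selected_set_matches_support_at_lambda_1se(self, path):
        i = int(np.argmin(np.abs(path.lambdas - path.lambda_1se)))
        support = {path.feature_names[j]
                   for j in np.flatnonzero(np.abs(path.coefs[:, i]) > 1e-10)}
        assert set(path.selected) == support

    def test_sparsity_broadly_monotone_in_penalty(self, path):
        nz = path.n_nonzero()
        # coarse check: strongest penalty end is at least as sparse
        assert nz[0] <= nz[-1]


class TestOverlap:
    def test_study_lists_give_eleven_of_fourteen(self):
        lasso14 = {
            "etiology", "cfv_recan", "d_dimer", "stent_diameter", "av_fistula",
            "ivc_extension", "eiv_recan", "crp", "anticoagulation", "aptt",
            "male", "surgery_time", "fib", "hospital_stay",
        }
        automl11 = {
            "etiology", "cfv_recan", "d_dimer", "stent_diameter", "av_fistula",
            "ivc_extension", "eiv_recan", "crp", "anticoagulation", "aptt", "male",
        }
        frac, inter = feature_overlap(lasso14, automl11)
        assert round(100 * frac, 2) == 78.57
        assert inter == automl11

    def test_identical_and_disjoint(self):
        assert feature_overlap({"a", "b"}, {"a", "b"})[0] == 1.0
        assert feature_overlap({"a", "b"}, {"c"})[0] == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            feature_overlap(set(), {"a"})


class TestShapley:
    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(0)
        w = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        f = lambda X: np.asarray(X) @ w
        Xb = rng.normal(size=(60, 5))
        Xe = rng.normal(size=(8, 5))
        S = shapley_values(f, Xe, Xb, method="exact")
        expected = w * (Xe - Xb.mean(axis=0))
        np.testing.assert_allclose(S.values, expected, atol=1e-6)

    def test_local_accuracy_for_both_methods(self):
        rng = np.random.default_rng(1)
        f = lambda X: np.tanh(np.asarray(X)).prod(axis=1)
        Xb = rng.normal(size=(30, 6))
        Xe = rng.normal(size=(5, 6))
        for method, kw in (("exact", {}), ("permutation", {"nsamples": 6})):
            S = shapley_values(f, Xe, Xb, method=method, seed=2, **kw)
            np.testing.assert_allclose(S.local_accuracy_gap(), 0.0, atol=1e-9)

    def test_sampled_estimator_agrees_with_exact_enumeration_d8(self):
        rng = np.random.default_rng(2)
        d = 8
        A = rng.normal(size=(d, d)) * 0.3
        f = lambda X: np.tanh(np.asarray(X) @ A).sum(axis=1)
        Xb = rng.normal(size=(20, d))
        Xe = rng.normal(size=(4, d))
        exact = shapley_values(f, Xe, Xb, method="exact")
        sampled = shapley_values(f, Xe, Xb, method="permutation", nsamples=40, seed=3)
        z = (sampled.values - exact.values) / np.maximum(sampled.se, 1e-12)
        assert np.abs(z).max() < 3.0

    def test_duplicated_features_receive_equal_importance(self):
        rng = np.random.default_rng(4)
        f = lambda X: np.asarray(X)[:, 0] + np.asarray(X)[:, 1]
        base = rng.normal(size=(40, 1))
        Xb = np.hstack([base, base])
        e = rng.normal(size=(6, 1))
        Xe = np.hstack([e, e])
        S = shapley_values(f, Xe, Xb, method="exact")
        np.testing.assert_allclose(S.values[:, 0], S.values[:, 1], atol=1e-9)

    def test_nsamples_guard(self):
        with pytest.raises(ValueError):
            shapley_values(lambda X: np.zeros(len(X)), np.zeros((1, 3)),
                           np.zeros((2, 3)), method="permutation", nsamples=1)


class TestImportance:
    def test_single_active_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        f = lambda X: 2.0 * np.asarray(X)[:, 2]
        S = shapley_values(f, rng.normal(size=(10, 4)), rng.normal(size=(30, 4)),
                          method="exact", feature_names=["a", "b", "c", "d"])
        df = shap_importance(S)
        assert df.feature.iloc[0] == "c"
        assert df.mean_abs_shap.iloc[1:].max() < 1e-9

    def test_ranking_invariant_to_sample_order(self):
        rng = np.random.default_rng(1)
        f = lambda X: np.asarray(X) @ np.array([1.0, 0.5, 0.2])
        Xe = rng.normal(size=(12, 3))
        Xb = rng.normal(size=(25, 3))
        S1 = shapley_values(f, Xe, Xb, method="exact")
        S2 = shapley_values(f, Xe[::-1], Xb, method="exact")
        assert shap_importance(S1).feature.tolist() == shap_importance(S2).feature.tolist()


class TestInteraction:
    def _shap_for(self, f, X, names):
        return shapley_values(f, X, X[:40], method="exact", feature_names=names)

    def test_additive_model_has_null_synergy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(150, 2))
        f = lambda Z: np.asarray(Z)[:, 0] + 0.5 * np.asarray(Z)[:, 1]
        S = self._shap_for(f, X, ["a", "b"])
        res = interaction_summary(S, X, ("a", "b"), (0.0, 0.0))
        assert abs(res.synergy_score) < max(2 * res.synergy_se, 1e-9)

    def test_product_term_detected_as_positive_synergy(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 2))
        f = lambda Z: (np.asarray(Z)[:, 0] > 0) * (np.asarray(Z)[:, 1] > 0) * 2.0
        S = self._shap_for(f, X, ["a", "b"])
        res = interaction_summary(S, X, ("a", "b"), (0.0, 0.0))
        assert res.synergy_score > 0.5

    def test_quadrant_counts_cover_all_samples(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 3))
        f = lambda Z: np.asarray(Z).sum(axis=1)
        S = shapley_values(f, X, X[:20], method="exact", feature_names=["a", "b", "c"])
        res = interaction_summary(S, X, ("a", "c"), (0.0, 0.0))
        assert sum(res.quadrant_count.values()) == 80

    def test_empty_quadrant_reported_absent(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [1.5, 1.2]])
        f = lambda Z: np.asarray(Z).sum(axis=1)
        S = shapley_values(f, X, X, method="exact", feature_names=["a", "b"])
        res = interaction_summary(S, X, ("a", "b"), (0.0, 0.0))
        assert res.quadrant_mean[("low", "low")] is None
        assert np.isnan(res.synergy_score)
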