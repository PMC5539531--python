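"""PLS-DA, cross-validation metrics, VIP scores and the PCA baseline."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from flavormine.latent import (
    PCAVarianceReducer,
    PLSDAClassifier,
    VIPRanking,
    auto_components,
    compute_vip,
    cross_validate_pls,
    fit_pca,
    fit_plsda,
    pca_reduce,
    rank_by_vip,
    training_r2,
)
from flavormine.latent import _one_hot
from flavormine.synthetic import GeneratorConfig, generate_dataset


def _random_problem(rng, n=30, p=8, k=3):
    X = rng.normal(size=(n, p))
    y = rng.integers(k, size=n)
    return X, y


class TestPLSDAFit:
    def test_scores_orthogonal_weights_unit(self, rng):
        X, y = _random_problem(rng)
        m = fit_plsda(X, y, 5)
        T = m.x_scores_
        G = np.abs(T.T @ T - np.diag((T**2).sum(axis=0)))
        norms = np.sqrt((T**2).sum(axis=0))
        assert G.max() < 1e-8 * norms.max() ** 2
        np.testing.assert_allclose((m.x_weights_**2).sum(axis=0), 1.0, atol=1e-10)

    def test_matches_sklearn_pls2_predictions(self, rng):
        # independent oracle: sklearn's NIPALS PLS2 on the same one-hot coding
        X, y = _random_problem(rng, n=40, p=6, k=3)
        A = 4
        ours = fit_plsda(X, y, A)
        Y = _one_hot(y, ours.classes_)
        ref = PLSRegression(n_components=A, scale=False, tol=1e-12, max_iter=5000)
        ref.fit(X, Y)
        X_new = rng.normal(size=(15, 6))
        np.testing.assert_allclose(
            ours.decision_function(X_new), ref.predict(X_new), atol=1e-8
        )

    def test_rank_one_data_gives_singular_direction(self, rng):
        u = rng.normal(size=25)
        v = rng.normal(size=6)
        X = np.outer(u, v)
        y = (u > np.median(u)).astype(int)
        m = fit_plsda(X, y, 1)
        t = m.x_scores_[:, 0]
        uc = u - u.mean()
        corr = abs(t @ uc) / (np.linalg.norm(t) * np.linalg.norm(uc))
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_component_count_errors(self, rng):
        X, y = _random_problem(rng, n=10, p=4)
        with pytest.raises(ValueError):
            fit_plsda(X, y, 0)
        with pytest.raises(ValueError, match="rank"):
            fit_plsda(X, y, 5)  # p = 4 < 5
        with pytest.raises(ValueError, match="class"):
            fit_plsda(X, np.zeros(10), 2)


class TestPLSDAPredict:
    def test_separable_limit_perfect_training_accuracy(self, crisp_dataset):
        table, _ = crisp_dataset
        m = fit_plsda(table.values, table.labels, 4)
        assert (m.predict(table.values) == table.labels).all()

    def test_duplicated_row_identical_predictions(self, rng):
        X, y = _random_problem(rng)
        m = fit_plsda(X, y, 3)
        row = np.tile(X[0], (5, 1))
        assert len(set(m.predict(row))) == 1

    def test_tie_decodes_to_first_class(self):
        m = PLSDAClassifier.__new__(PLSDAClassifier)
        m.classes_ = np.array(["a", "b", "c"])
        scores = np.array([[0.4, 0.4, 0.1]])
        assert m.classes_[np.argmax(scores, axis=1)][0] == "a"

    def test_dimension_mismatch(self, rng):
        X, y = _random_problem(rng)
        m = fit_plsda(X, y, 2)
        with pytest.raises(ValueError, match="column count"):
            m.predict(X[:, :4])


class TestCrossValidation:
    def test_separable_data_high_cv(self, crisp_dataset):
        table, _ = crisp_dataset
        res = cross_validate_pls(table.values, table.labels, 8, folds=5, seed=0)
        assert res.cv_percent_curve.max() > 95.0

    def test_pure_noise_low_cv(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            X = rng.normal(size=(60, 10))
            y = np.repeat(np.arange(3), 20)
            res = cross_validate_pls(X, y, 5, folds=5, seed=seed)
            hits += res.cv_percent_curve.max() <= 10.0
        assert hits >= 9

    def test_leave_one_out_accepted(self, rng):
        X, y = _random_problem(rng, n=20, p=4)
        res = cross_validate_pls(X, y, 2, folds=20, seed=0)
        assert res.folds == 20

    def test_folds_out_of_range(self, rng):
        X, y = _random_problem(rng, n=20)
        for folds in (1, 21):
            with pytest.raises(ValueError, match="folds"):
                cross_validate_pls(X, y, 2, folds=folds)

    def test_training_r2_dominates_cv_on_clean_data(self, crisp_dataset):
        table, _ = crisp_dataset
        a, res = auto_components(table.values, table.labels, seed=1)
        m = fit_plsda(table.values, table.labels, a)
        r2 = training_r2(m, table.values, table.labels)
        assert r2 >= res.cv_percent_curve[a - 1] - 5.0

    def test_rmsecv_consistent_with_cv_percent(self, rng):
        # both are monotone transforms of the same PRESS
        X, y = _random_problem(rng, n=40)
        res = cross_validate_pls(X, y, 4, folds=5, seed=2)
        Y = _one_hot(y, np.unique(y))
        tss = ((Y - Y.mean(axis=0)) ** 2).sum()
        press = (1 - res.cv_percent_curve / 100) * tss
        np.testing.assert_allclose(
            res.rmsecv_curve, np.sqrt(press / Y.size), atol=1e-10
        )


class TestVIP:
    def test_sum_of_squares_equals_p(self, rng):
        for _ in range(20):
            p = int(rng.integers(2, 21))
            X, y = _random_problem(rng, n=30, p=p)
            a = int(rng.integers(1, min(p, 5) + 1))
            vip = compute_vip(fit_plsda(X, y, a))
            assert (vip.scores**2).sum() == pytest.approx(p, abs=1e-8)

    def test_single_variable_vip_is_one(self, rng):
        X = rng.normal(size=(20, 1))
        y = (X[:, 0] > 0).astype(int)
        vip = compute_vip(fit_plsda(X, y, 1))
        assert vip.scores[0] == pytest.approx(1.0)

    def test_brute_force_formula_oracle(self, rng):
        X, y = _random_problem(rng, n=20, p=8)
        m = fit_plsda(X, y, 4)
        vip = compute_vip(m)
        # independent element-wise evaluation of the definition
        W, T, Q = m.x_weights_, m.x_scores_, m.y_loadings_
        p, A = W.shape
        ss = [sum(Q[k, a] ** 2 for k in range(Q.shape[0])) * (T[:, a] @ T[:, a])
              for a in range(A)]
        expected = [
            np.sqrt(p * sum(ss[a] * (W[j, a] / np.linalg.norm(W[:, a])) ** 2
                            for a in range(A)) / sum(ss))
            for j in range(p)
        ]
        np.testing.assert_allclose(vip.scores, expected, atol=1e-10)

    def test_recovers_informative_variables(self):
        # all 12 planted variables inside the top 14 VIP ranks in >= 8/10 seeds
        hits = 0
        for seed in range(10):
            table, truth = generate_dataset(GeneratorConfig(), seed=400 + seed)
            a, _ = auto_components(table.values, table.labels, seed=seed)
            vip = compute_vip(
                fit_plsda(table.values, table.labels, a), table.var_names
            )
            hits += set(truth.informative_set) <= set(vip.order[:14])
        assert hits >= 8

    def test_ranking_stable_ties(self):
        r = VIPRanking(var_names=["a", "b", "c"], scores=[1.0, 2.0, 2.0])
        assert rank_by_vip(r) == ["b", "c", "a"]


class TestPCA:
    def test_ratios_match_eigenvalue_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        model = fit_pca(X)
        evals = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
        np.testing.assert_allclose(
            model.explained_variance_ratio_, evals / evals.sum(), atol=1e-10
        )
        assert model.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-10)

    def test_equal_variance_directions_need_all_components(self, rng):
        # exactly isotropic sample covariance: every ratio is 1/p
        n, p = 41, 20
        A = rng.normal(size=(n, p))
        A -= A.mean(axis=0)
        U, _, Vt = np.linalg.svd(A, full_matrices=False)
        X = U @ Vt  # equal singular values, still column-centered
        model = PCAVarianceReducer(cum_threshold=0.99).fit(X)
        assert model.n_components_ == 20  # 19 components only reach 95%

    def test_single_direction_data(self, rng):
        X = np.outer(rng.normal(size=12), rng.normal(size=5))
        model = PCAVarianceReducer(cum_threshold=0.99).fit(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)
        assert model.n_components_ == 1

    def test_reconstruction_error_equals_discarded_eigenvalues(self, rng):
        X = rng.normal(size=(30, 8)) * np.arange(1, 9)
        model = fit_pca(X)
        scores = pca_reduce(model, X, cum_threshold=0.8)
        m = scores.shape[1]
        recon = scores @ model.loadings_[:m] + model.mean_
        sse = ((X - recon) ** 2).sum() / (X.shape[0] - 1)
        discarded = model.pca_.explained_variance_[m:].sum()
        assert sse == pytest.approx(discarded, abs=1e-8)

    def test_threshold_validation(self, rng):
        X = rng.normal(size=(10, 4))
        model = fit_pca(X)
        for thr in (0.0, 1.0001):
            with pytest.raises(ValueError):
                pca_reduce(model, X, cum_threshold=thr)
        with pytest.raises(ValueError, match="2 samples"):
            PCAVarianceReducer().fit(X[:1])
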