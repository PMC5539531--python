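"""RBF-SVM (GA-tuned), random forest, ELM, and the sweep-and-average protocol."""

import numpy as np
import pytest

from flavormine.classifiers import (
    DEFAULT_SWEEP_GRID,
    ELMClassifier,
    GAOptConfig,
    default_mtry,
    ga_tune_svm,
    rbf_kernel,
    sweep_and_average,
    train_elm,
    train_rf,
    train_svm,
)
from flavormine.data import normalize_apply, normalize_fit, stratified_split


@pytest.fixture(scope="module")
def crisp_split(crisp_dataset):
    table, _ = crisp_dataset
    plan = stratified_split(table, 0.8, seed=1)
    train = table.select_samples(plan.train_indices)
    test = table.select_samples(plan.test_indices)
    scaler = normalize_fit(train)
    return normalize_apply(scaler, train), normalize_apply(scaler, test)


class TestRBFKernel:
    def test_unit_diagonal_and_symmetry(self, rng):
        X = rng.normal(size=(6, 4))
        for variant in ("squared", "literal"):
            K = rbf_kernel(X, X, g=0.7, variant=variant)
            np.testing.assert_allclose(np.diag(K), 1.0)
            np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_zero_width_gives_all_ones(self, rng):
        X = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(rbf_kernel(X, X, g=0.0), np.ones((5, 5)))

    def test_positive_semidefinite(self, rng):
        X = rng.normal(size=(6, 3))
        for variant in ("squared", "literal"):
            K = rbf_kernel(X, X, g=0.5, variant=variant)
            assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_width_reading(self):
        # squared variant is exp(-g d^2); literal is exp(-2 g d)
        X1, X2 = np.array([[0.0]]), np.array([[2.0]])
        assert rbf_kernel(X1, X2, g=0.25)[0, 0] == pytest.approx(np.exp(-1.0))
        assert rbf_kernel(X1, X2, g=0.25, variant="literal")[0, 0] == pytest.approx(
            np.exp(-1.0)
        )

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros((2, 2)), np.zeros((2, 2)), g=-1.0)


class TestSVM:
    def test_separable_training_accuracy(self, rng):
        X = np.vstack([rng.normal(size=(20, 2)) + 4, rng.normal(size=(20, 2)) - 4])
        y = np.repeat([0, 1], 20)
        model = train_svm(X, y, c=100.0, g=0.5)
        assert (model.predict(X) == y).all()

    def test_dual_feasibility_on_fits(self, crisp_split, rng):
        train, _ = crisp_split
        fits = [
            train_svm(train.values, train.labels, c=10.0, g=0.1),
            train_svm(train.values, train.labels, c=0.5, g=1.0),
            train_svm(
                rng.normal(size=(30, 4)), np.repeat([0, 1, 2], 10), c=5.0, g=0.3
            ),
        ]
        for model in fits:
            for checks in model.dual_feasibility_.values():
                assert checks["equality_residual"] < 1e-6
                assert checks["box_violation"] <= 1e-6

    def test_overlapping_points_soft_margin(self):
        X = np.array([[0.0, 0.0]] * 6)
        y = np.array([0, 1] * 3)
        model = train_svm(X, y, c=0.5, g=1.0)  # must not fail
        assert model.predict(X).shape == (6,)

    def test_degenerate_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="single sample"):
            train_svm(X, y, c=1.0, g=1.0)

    def test_multiclass_votes(self, crisp_split):
        train, test = crisp_split
        model = train_svm(train.values, train.labels, c=10.0, g=0.05)
        acc = np.mean(model.predict(test.values) == test.labels)
        assert acc >= 0.95


class TestGATuneSVM:
    def test_returns_values_in_range_and_good_fit(self, crisp_split):
        train, _ = crisp_split
        cfg = GAOptConfig(generations=8, population=8, seed=0, g_scale="log")
        c, g, cv_acc, history = ga_tune_svm(train.values, train.labels, cfg)
        assert 0 < c <= 100
        assert 0 <= g <= 1000
        assert cv_acc >= 95.0
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_fixed_seed_reproducible(self, crisp_split):
        train, _ = crisp_split
        cfg = GAOptConfig(generations=3, population=6, seed=5, g_scale="log")
        assert ga_tune_svm(train.values, train.labels, cfg) == ga_tune_svm(
            train.values, train.labels, cfg
        )

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            GAOptConfig(c_range=(5.0, 5.0))


class TestDefaultMtry:
    @pytest.mark.parametrize(
        "p,expected",
        [(20, 4), (10, 3), (12, 3), (1, 1), (3, 1), (4, 2), (8, 2), (9, 3), (15, 3), (16, 4)],
    )
    def test_floor_sqrt_rule(self, p, expected):
        assert default_mtry(p) == expected

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            default_mtry(0)


class TestRandomForest:
    def test_single_class_always_predicted(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array(["only"] * 10)
        model = train_rf(X, y, n_trees=5, seed=0)
        assert (model.predict(X) == "only").all()

    def test_fixed_seed_reproducible(self, crisp_split):
        train, test = crisp_split
        a = train_rf(train.values, train.labels, n_trees=20, mtry=4, seed=3)
        b = train_rf(train.values, train.labels, n_trees=20, mtry=4, seed=3)
        np.testing.assert_array_equal(a.predict(test.values), b.predict(test.values))

    def test_separable_test_accuracy(self, crisp_split):
        train, test = crisp_split
        model = train_rf(train.values, train.labels, n_trees=100, mtry=4, seed=0)
        assert np.mean(model.predict(test.values) == test.labels) >= 0.9

    def test_mtry_out_of_range(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="mtry"):
            train_rf(X, y, n_trees=5, mtry=4)


class TestELM:
    def test_beta_matches_least_squares_oracle(self, rng):
        for _ in range(10):
            n, p, h = 25, 6, int(rng.integers(3, 40))
            X = rng.normal(size=(n, p))
            y = rng.integers(3, size=n)
            model = train_elm(X, y, n_hidden=h, seed=int(rng.integers(2**31)))
            H = model._activate(X @ model.input_weights_ + model.biases_)
            T = np.zeros((n, 3))
            T[np.arange(n), y] = 1.0
            ours = np.linalg.norm(H @ model.beta_ - T)
            oracle = np.linalg.norm(
                H @ np.linalg.lstsq(H, T, rcond=None)[0] - T
            )
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_square_invertible_interpolates(self, rng):
        n = 12
        X = rng.normal(size=(n, 4))
        y = rng.integers(2, size=n)
        model = train_elm(X, y, n_hidden=n, seed=0)
        H = model._activate(X @ model.input_weights_ + model.biases_)
        if np.linalg.matrix_rank(H) == n:  # the generic case
            T = np.zeros((n, 2))
            T[np.arange(n), y] = 1.0
            assert np.linalg.norm(H @ model.beta_ - T) < 1e-6

    def test_residual_is_local_minimum(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.integers(3, size=30)
        model = train_elm(X, y, n_hidden=10, seed=1)
        H = model._activate(X @ model.input_weights_ + model.biases_)
        T = np.zeros((30, 3))
        T[np.arange(30), y] = 1.0
        base = np.linalg.norm(H @ model.beta_ - T)
        for _ in range(100):
            eps = rng.normal(scale=1e-4, size=model.beta_.shape)
            assert np.linalg.norm(H @ (model.beta_ + eps) - T) >= base - 1e-12

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.integers(2, size=20)
        a = train_elm(X, y, n_hidden=8, seed=7)
        b = train_elm(X, y, n_hidden=8, seed=7)
        np.testing.assert_array_equal(a.beta_, b.beta_)

    def test_separable_test_accuracy(self, crisp_split):
        train, test = crisp_split
        model = train_elm(train.values, train.labels, n_hidden=40, seed=0)
        assert np.mean(model.predict(test.values) == test.labels) >= 0.95

    def test_bad_params(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError):
            train_elm(X, y, n_hidden=0)
        with pytest.raises(ValueError):
            ELMClassifier(n_hidden=4, activation="relu6").fit(X, y)


class TestSweepAndAverage:
    def test_default_grid_has_50_points(self):
        assert len(DEFAULT_SWEEP_GRID) == 50
        assert DEFAULT_SWEEP_GRID[0] == 2 and DEFAULT_SWEEP_GRID[-1] == 100

    def test_deterministic_trainer_single_repeat(self, crisp_split):
        train, test = crisp_split
        model = train_svm(train.values, train.labels, c=10.0, g=0.05)
        trainer = lambda v, s: model
        sweep = sweep_and_average(
            trainer, [1], train.values, train.labels, test.values, test.labels,
            repeats=1, seed=0,
        )
        single = np.mean(model.predict(test.values) == test.labels) * 100
        assert sweep.mean_accuracy[0] == pytest.approx(single)

    def test_elm_sweep_reaches_high_accuracy(self, crisp_split):
        train, test = crisp_split
        sweep = sweep_and_average(
            lambda v, s: train_elm(train.values, train.labels, n_hidden=v, seed=s),
            [10, 30, 50], train.values, train.labels, test.values, test.labels,
            repeats=3, seed=0,
        )
        assert sweep.best_mean >= 95.0

    def test_tie_prefers_smallest_grid_value(self):
        class Fixed:
            def predict(self, X):
                return np.zeros(len(X))

        sweep = sweep_and_average(
            lambda v, s: Fixed(), [4, 2, 8],
            None, None, np.zeros((5, 1)), np.zeros(5),
            repeats=2, seed=0,
        )
        assert sweep.best_value == 4  # first grid entry as given

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            sweep_and_average(lambda v, s: None, [], None, None, None, None)
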