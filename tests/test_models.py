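"""Classifier contracts: kernels, lasso limits, KNN oracle, RF, tuning."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from phenonoise.models import (
    KNNClassifier,
    LassoLogistic,
    ModelSpec,
    RandomForest,
    SVMClassifier,
    balanced_accuracy,
    default_grid,
    kernel,
    knn_predict,
    lasso_lambda_path,
    tune,
)


def logistic_nll(params, X, y):
    """Unpenalised negative binomial log-likelihood (independent oracle)."""
    mu, beta = params[0], params[1:]
    eta = mu + X @ beta
    return np.sum(np.logaddexp(0.0, eta)) - np.sum(y * eta)


@pytest.fixture(scope="module")
def toy_40x5():
    """Non-separable 40 x 5 dose matrix with a weak linear signal."""
    rng = np.random.default_rng(12)
    X = rng.integers(0, 3, size=(40, 5)).astype(float)
    eta = -0.5 + 0.8 * X[:, 0] - 0.6 * X[:, 2]
    y = (rng.random(40) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)
    assert 0 < y.sum() < 40
    return X, y


class TestKernel:
    def test_linear_inner_product(self):
        assert kernel([1, 2], [2, 0], "linear") == pytest.approx(2.0)

    def test_radial_identity_point(self):
        assert kernel([1, 2, 0], [1, 2, 0], "radial", gamma=3.7) == pytest.approx(1.0)

    def test_radial_known_value(self):
        assert kernel([0, 0], [1, 1], "radial", gamma=0.5) == pytest.approx(
            np.exp(-1.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kernel([1, 2], [1, 2, 3], "linear")


class TestLasso:
    def test_huge_penalty_gives_intercept_only_majority_model(self, toy_40x5):
        X, y = toy_40x5
        model = LassoLogistic(lam=1e6).fit(X, y)
        assert np.all(model.coef_ == 0.0)
        majority = int(y.mean() > 0.5)
        assert np.all(model.predict(X) == majority)

    def test_tiny_penalty_matches_unpenalised_mle(self, toy_40x5):
        X, y = toy_40x5
        model = LassoLogistic(lam=1e-6, max_iter=200000, tol=1e-12).fit(X, y)
        x0 = np.zeros(X.shape[1] + 1)
        res = minimize(logistic_nll, x0, args=(X, y.astype(float)),
                       method="BFGS", options={"gtol": 1e-10, "maxiter": 5000})
        assert res.success or np.linalg.norm(res.jac) < 1e-6
        assert model.intercept_ == pytest.approx(res.x[0], abs=1e-3)
        assert model.coef_ == pytest.approx(res.x[1:], abs=1e-3)

    def test_boundary_probability_classified_non_carrier(self):
        model = LassoLogistic(lam=1.0)
        model.coef_ = np.zeros(2)
        model.intercept_ = 0.0  # p(x) = 0.5 exactly, everywhere
        assert np.allclose(model.predict_proba(np.zeros((3, 2))), 0.5)
        assert np.all(model.predict(np.zeros((3, 2))) == 0)

    def test_support_size_non_increasing_along_penalty_path(self, toy_40x5):
        X, y = toy_40x5
        lams = lasso_lambda_path(X, y, n_points=10, decades=3.0)
        sizes = [int((LassoLogistic(lam=l).fit(X, y).coef_ != 0).sum())
                 for l in lams]  # descending penalties
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))
        # strictly above lambda_max every effect is zero (KKT condition)
        above = LassoLogistic(lam=1.05 * lams[0]).fit(X, y)
        assert int((above.coef_ != 0).sum()) == 0

    def test_single_class_labels_rejected(self, toy_40x5):
        X, _ = toy_40x5
        with pytest.raises(ValueError, match="single class"):
            LassoLogistic(lam=1.0).fit(X, np.zeros(len(X)))


class TestSVM:
    def test_separable_clouds_zero_training_error(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0], 0.3, size=(20, 2))
        b = rng.normal([4, 4], 0.3, size=(20, 2))
        X = np.vstack([a, b])
        y = np.repeat([0, 1], 20)
        model = SVMClassifier("linear", C=10.0).fit(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_xor_radial_separates_linear_cannot(self):
        proto = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0], dtype=np.int8)
        X = np.repeat(proto, 10, axis=0)
        yy = np.repeat(y, 10)
        radial = SVMClassifier("radial", C=100.0, gamma=2.0).fit(X, yy)
        assert np.array_equal(radial.predict(proto), y)
        # no linear rule separates XOR: enumerate sign patterns of every
        # w1*x1 + w2*x2 + b over a sign/threshold sweep
        best = 4
        for w1 in np.linspace(-1, 1, 21):
            for w2 in np.linspace(-1, 1, 21):
                scores = proto @ [w1, w2]
                for b in np.unique(np.concatenate([scores, scores - 1e-9,
                                                   scores + 1e-9])):
                    errs = int(((scores > b).astype(int) != y).sum())
                    best = min(best, errs)
        assert best >= 1
        linear = SVMClassifier("linear", C=100.0).fit(X, yy)
        assert (linear.predict(proto) != y).sum() >= 1

    def test_duplicating_points_keeps_predictions_on_separable_data(self):
        rng = np.random.default_rng(5)
        a = rng.normal([0, 0], 0.2, size=(15, 2))
        b = rng.normal([3, 3], 0.2, size=(15, 2))
        X = np.vstack([a, b])
        y = np.repeat([0, 1], 15)
        queries = rng.uniform(-1, 4, size=(50, 2))
        single = SVMClassifier("linear", C=1.0).fit(X, y)
        doubled = SVMClassifier("linear", C=1.0).fit(np.vstack([X, X]),
                                                     np.concatenate([y, y]))
        assert np.array_equal(single.predict(queries), doubled.predict(queries))


class TestKNN:
    def test_euclidean_three_four_five(self):
        X = np.array([[3.0, 4.0]])
        d2 = ((np.array([[0.0, 0.0]]) - X) ** 2).sum()
        assert np.sqrt(d2) == pytest.approx(5.0)
        # the classifier ranks by this distance: a 3-4-5 point beats a 6-8-10
        Xt = np.array([[3.0, 4.0], [6.0, 8.0]])
        assert knn_predict(Xt, [1, 0], [[0.0, 0.0]], K=1)[0] == 1

    def test_k1_exact_match_returns_its_label(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(30, 6)).astype(float)
        y = rng.integers(0, 2, size=30)
        assert knn_predict(X, y, X[17], K=1)[0] == y[17]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            Xt = rng.integers(0, 3, size=(60, 10)).astype(float)
            yt = rng.integers(0, 2, size=60)
            Xq = rng.integers(0, 3, size=(20, 10)).astype(float)
            got = knn_predict(Xt, yt, Xq, K=5)
            for q in range(20):
                ranked = sorted(range(60),
                                key=lambda i: (np.sum((Xq[q] - Xt[i]) ** 2), i))
                vote = sum(yt[i] for i in ranked[:5])
                assert got[q] == (1 if vote > 2 else 0)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            knn_predict(np.zeros((4, 2)), [0, 1, 0, 1], [[0, 0]], K=2)

    def test_k_larger_than_training_rejected(self):
        with pytest.raises(ValueError, match="training"):
            knn_predict(np.zeros((3, 2)), [0, 1, 0], [[0, 0]], K=5)


class TestRandomForest:
    def test_default_subset_size_near_sqrt_m(self):
        assert default_grid("rf", 1512)["s"] == [20, 39, 78]
        assert int(np.ceil(np.sqrt(1512))) == 39

    def test_single_unbagged_tree_reduces_to_decision_tree(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, size=(80, 6)).astype(float)
        y = (X[:, 0] + X[:, 3] > 2).astype(np.int8)
        Xq = rng.integers(0, 3, size=(40, 6)).astype(float)
        rf = RandomForest(B=1, s=6, seed=0, bootstrap=False).fit(X, y)
        tree = DecisionTreeClassifier(random_state=0).fit(X, y)
        assert np.array_equal(rf.predict(X), y)
        assert np.array_equal(rf.predict(Xq), tree.predict(Xq))

    def test_interpolates_separable_training_data(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 3, size=(100, 20)).astype(float)
            y = (X[:, 2] >= 1).astype(np.int8)
            rf = RandomForest(B=500, s=4, seed=seed).fit(X, y)
            assert (rf.predict(X) == y).mean() >= 0.99

    def test_vote_tie_goes_to_non_carrier(self):
        rf = RandomForest(B=2, s=1, seed=0)

        class HalfVotes:
            def predict_proba(self, X):
                return np.tile([0.5, 0.5], (len(X), 1))

        rf._est = HalfVotes()
        assert np.all(rf.predict(np.zeros((4, 3))) == 0)

    def test_oversized_feature_subset_rejected(self):
        X = np.zeros((10, 3))
        X[:5] = 1.0
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="s must be"):
            RandomForest(B=5, s=4).fit(X, y)


class TestBalancedAccuracy:
    def test_perfect_classifier_scores_one(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        assert balanced_accuracy(y, y) == pytest.approx(1.0)

    def test_all_majority_on_imbalanced_data_scores_half(self):
        y = np.array([1] + [0] * 24)
        assert balanced_accuracy(y, np.zeros(25)) == pytest.approx(0.5)


class TestTune:
    def test_single_grid_point_skips_cv_and_refits_directly(self, toy_40x5):
        X, y = toy_40x5
        tuned = tune(ModelSpec("knn", {"K": [3]}), X, y, folds=10, seed=0)
        assert tuned.params == {"K": 3}
        direct = KNNClassifier(K=3).fit(X, y)
        assert np.array_equal(tuned.predict(X), direct.predict(X))
        assert tuned.cv_table.empty

    def test_knn_selection_matches_handrolled_cv_with_shared_folds(self):
        rng = np.random.default_rng(21)
        cfg_X = rng.integers(0, 3, size=(120, 12)).astype(float)
        y = (cfg_X[:, 0] + cfg_X[:, 1] + rng.normal(0, 0.8, 120) > 2.5
             ).astype(np.int8)
        grid = [1, 3, 5, 7]
        seed = 4
        tuned = tune(ModelSpec("knn", {"K": grid}), cfg_X, y, folds=5,
                     seed=seed)
        # independent CV loop with the same fold generator
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        splits = list(skf.split(cfg_X, y))
        means = []
        for K in grid:
            scores = []
            for tr, va in splits:
                pred = knn_predict(cfg_X[tr], y[tr], cfg_X[va], K)
                scores.append(balanced_accuracy(y[va], pred))
            means.append(np.mean(scores))
        assert tuned.params["K"] == grid[int(np.argmax(means))]
        assert tuned.cv_balanced_accuracy == pytest.approx(max(means))

    def test_too_few_carriers_for_stratification_errors(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(50, 4)).astype(float)
        y = np.zeros(50, dtype=np.int8)
        y[:3] = 1
        with pytest.raises(ValueError, match="stratification"):
            tune(ModelSpec("knn", {"K": [1, 3]}), X, y, folds=10)

    def test_invalid_grid_keys_and_values_rejected(self):
        with pytest.raises(ValueError, match="not valid"):
            ModelSpec("knn", {"C": [1.0]})
        with pytest.raises(ValueError, match="odd"):
            ModelSpec("knn", {"K": [2]})
        with pytest.raises(ValueError, match="positive"):
            ModelSpec("svm_linear", {"C": [0.0]})
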