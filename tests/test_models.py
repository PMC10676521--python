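"""Classifiers, splitting, cross-validation and the Bayesian optimizer."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from citegate.classifiers import HyperParams, MarkerClassifier, NumpyMLP
from citegate.model import evaluate_predictions, split_train_test
from citegate.optimize import Dimension, OptimizationError, bayes_optimize


def xor_toy():
    """Fixed 40-point XOR layout: linearly inseparable, RBF-separable."""
    rng = np.random.default_rng(0)
    centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
    X = np.vstack([c + rng.normal(0, 0.08, (10, 2)) for c in centers])
    y = np.array([0] * 20 + [1] * 20)
    return X, y


class TestSplit:
    def test_cardinality_and_disjointness(self):
        train, test = split_train_test(100, test_size=0.2, seed=42)
        assert len(train) == 80 and len(test) == 20
        assert len(set(train) & set(test)) == 0
        assert sorted(np.concatenate([train, test])) == list(range(100))

    def test_same_seed_identical(self):
        a = split_train_test(500, seed=42)
        b = split_train_test(500, seed=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_different_seeds_differ(self):
        a = split_train_test(500, seed=42)
        b = split_train_test(500, seed=43)
        assert not np.array_equal(a[1], b[1])


class TestStratifiedFolds:
    def test_fold_class_balance(self):
        y = np.array([1] * 70 + [0] * 30)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, test_idx in skf.split(np.zeros(100), y):
            assert abs((y[test_idx] == 1).sum() - 14) <= 1

    def _separable_cv_inputs(self):
        """Planted two-group data where feature selection finds the signal."""
        rng = np.random.default_rng(30)
        n, g = 200, 40
        y = np.array([1] * 80 + [0] * 120)
        corrected = rng.poisson(5.0, size=(n, g)).astype(float)
        corrected[y == 1, :5] = rng.poisson(25.0, size=(80, 5))  # strong DE block
        X = (corrected - corrected.mean(axis=0)) / corrected.std(axis=0)
        anchor = rng.normal(size=n)
        X[:, 6] = anchor + rng.normal(0, 0.3, n)
        X[:, 5] = anchor
        genes = ["HNRNPLL" if i == 5 else f"G{i}" for i in range(g)]
        return X, corrected, y, genes

    def test_separable_data_scores_high_and_is_deterministic(self):
        from citegate.model import stratified_kfold_score

        X, corrected, y, genes = self._separable_cv_inputs()
        hp = HyperParams(model_kind="svm_rbf", t_de_upper=1.0, t_de_lower=-1.0,
                         p_hn=0.1, c_svm=10.0, gamma=0.05)
        score = stratified_kfold_score(hp, X, corrected, y, genes, k=5, seed=3)
        assert score.metric == "accuracy"
        assert score.mean >= 0.99
        again = stratified_kfold_score(hp, X, corrected, y, genes, k=5, seed=3)
        assert score.fold_values == again.fold_values
        assert score.mean == np.mean(score.fold_values)

    def test_empty_feature_set_scores_worst(self):
        from citegate.model import stratified_kfold_score

        X, corrected, y, genes = self._separable_cv_inputs()
        hp = HyperParams(model_kind="svm_rbf", t_de_upper=3.9, t_de_lower=-3.9,
                         p_hn=1e-6, c_svm=10.0, gamma=0.05)
        score = stratified_kfold_score(hp, X, corrected, y, genes, k=5, seed=3)
        assert score.mean == 0.0


class TestClassifiers:
    def test_rbf_beats_linear_on_xor(self):
        X, y = xor_toy()
        hp = HyperParams(model_kind="svm_rbf", c_svm=10.0, gamma=1.0)
        rbf = MarkerClassifier("svm_rbf", hp).fit(X, y)
        assert (rbf.predict(X) == y).mean() == 1.0
        hp_lin = HyperParams(model_kind="svm_linear", c_svm=10.0)
        lin = MarkerClassifier("svm_linear", hp_lin).fit(X, y)
        assert (lin.predict(X) == y).mean() <= 0.75

    def test_stack_reproduces_agreeing_bases(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-2, 0.3, (30, 3)), rng.normal(2, 0.3, (30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        hp = HyperParams(model_kind="stack", c_svm=5.0, gamma=0.5, c_lr=1.0)
        stack = MarkerClassifier("stack", hp).fit(X, y)
        base_lr = stack.base_lr_.predict(stack._transform(X))
        base_svm = stack.base_svm_.predict(stack._transform(X))
        assert np.array_equal(base_lr, base_svm)  # easy problem: bases agree
        assert np.array_equal(stack.predict(X), base_lr)

    @pytest.mark.parametrize("kind", ["lr", "svm_linear", "svm_rbf", "stack", "mlp"])
    def test_all_kinds_learn_separable_data(self, kind):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(-1.5, 0.4, (60, 4)), rng.normal(1.5, 0.4, (60, 4))])
        y = np.array([0] * 60 + [1] * 60)
        hp = HyperParams(model_kind=kind, c_svm=5.0, gamma=0.3, c_lr=1.0,
                         n_layers=2, n_nodes=32, eta=5e-3, rho=0.2)
        clf = MarkerClassifier(kind, hp, seed=0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.99

    def test_single_class_labels_rejected(self):
        hp = HyperParams(model_kind="lr")
        with pytest.raises(ValueError, match="single class"):
            MarkerClassifier("lr", hp).fit(np.zeros((10, 2)), np.zeros(10, dtype=int))

    def test_mlp_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 5))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        a = NumpyMLP(seed=11).fit(X, y).predict_proba(X)
        b = NumpyMLP(seed=11).fit(X, y).predict_proba(X)
        assert np.array_equal(a, b)

    def test_mlp_dropout_off_at_prediction(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] > 0).astype(int)
        mlp = NumpyMLP(rho=0.5, seed=2).fit(X, y)
        assert np.array_equal(mlp.predict_proba(X), mlp.predict_proba(X))


class TestBayesOptimize:
    def test_finds_quadratic_maximum(self):
        target = 0.3

        def objective(params):
            return 1.0 - (params["x"] - target) ** 2

        result = bayes_optimize(objective, [Dimension("x", 0.0, 1.0)],
                                max_iter=15, seed=1)
        assert abs(result.best_params["x"] - target) < 0.05

    def test_infinite_ei_tol_stops_after_initial_design(self):
        calls = []

        def objective(params):
            calls.append(params)
            return params["x"]

        result = bayes_optimize(objective, [Dimension("x", 0.0, 1.0)],
                                max_iter=30, ei_tol=np.inf, seed=0)
        assert len(calls) == 5  # the space-filling design only
        assert result.stopped_early

    def test_same_seed_identical_trace(self):
        def objective(params):
            return np.sin(3 * params["x"]) + params["y"]

        dims = [Dimension("x", 0.0, 2.0), Dimension("y", 0.0, 1.0)]
        a = bayes_optimize(objective, dims, max_iter=12, seed=9)
        b = bayes_optimize(objective, dims, max_iter=12, seed=9)
        assert a.trace == b.trace

    def test_respects_max_iter_budget(self):
        calls = []

        def objective(params):
            calls.append(1)
            return np.cos(params["x"])

        bayes_optimize(objective, [Dimension("x", -3.0, 3.0)], max_iter=10, seed=2)
        assert len(calls) <= 10

    def test_all_zero_objective_degenerate(self):
        with pytest.raises(OptimizationError, match="degenerate"):
            bayes_optimize(lambda p: 0.0, [Dimension("x", 0.0, 1.0)],
                           max_iter=8, seed=0)

    def test_integer_dimension_rounds(self):
        seen = []

        def objective(params):
            seen.append(params["n"])
            return -abs(params["n"] - 2)

        bayes_optimize(objective, [Dimension("n", 1, 3, integer=True)],
                       max_iter=6, seed=0)
        assert all(float(v).is_integer() for v in seen)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0, 1])
        out = evaluate_predictions(y, y, scores=y.astype(float))
        assert out["accuracy"] == 1.0 and out["roc_auc"] == 1.0

    def test_hand_computed_confusion(self):
        # TP=3 FP=1 FN=2 TN=4 -> precision .75, recall .6
        y_true = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        out = evaluate_predictions(y_true, y_pred)
        assert out["precision"] == pytest.approx(0.75)
        assert out["recall"] == pytest.approx(0.6)

    def test_coin_flip_near_half(self):
        rng = np.random.default_rng(123)
        y = rng.integers(0, 2, 10000)
        pred = rng.integers(0, 2, 10000)
        scores = rng.random(10000)
        out = evaluate_predictions(y, pred, scores)
        assert 0.48 <= out["accuracy"] <= 0.52
        assert 0.48 <= out["roc_auc"] <= 0.52

    def test_no_positive_instances_undefined_not_zero(self):
        y_true = np.zeros(10, dtype=int)
        y_pred = np.zeros(10, dtype=int)
        out = evaluate_predictions(y_true, y_pred)
        assert out["precision"] is None and out["recall"] is None
        assert out["accuracy"] == 1.0

    def test_per_cluster_misclassification(self):
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.array([1, 0, 0, 0])
        out = evaluate_predictions(y_true, y_pred, clusters=np.array(["a", "a", "b", "b"]))
        by_cluster = {r["cluster"]: r["misclassified_pct"] for r in out["per_cluster"]}
        assert by_cluster == {"a": 50.0, "b": 0.0}
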