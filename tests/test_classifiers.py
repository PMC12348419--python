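import numpy as np
import pytest
from scipy import stats
from sklearn.datasets import make_blobs
from sklearn.metrics import balanced_accuracy_score

from transpred.classifiers import (
    FnnConfig,
    SvmConfig,
    anova_f_scores,
    class_weights,
    fit_fnn,
    fit_svm,
    load_model,
    predict,
    rbf_gamma,
    save_model,
    select_top_k,
    variance_filter,
)
from transpred.feature_assembly import FeatureMatrix


def as_matrix(X, feature_id="X"):
    return FeatureMatrix(
        sample_ids=tuple(f"S{i:03d}" for i in range(len(X))),
        feature_names=tuple(f"f{j:04d}" for j in range(X.shape[1])),
        values=X,
        feature_id=feature_id,
    )


def blobs_matrix(n=60, d=10, seed=4, sep=8.0):
    X, y = make_blobs(
        n_samples=n, centers=2, n_features=d, cluster_std=1.0,
        center_box=(-sep, sep), random_state=seed,
    )
    labels = np.where(y == 1, "pos", "neg")
    return as_matrix(X), labels


class TestVarianceFilter:
    def test_constant_column_removed(self):
        X = np.hstack([np.random.default_rng(0).normal(size=(10, 3)), np.ones((10, 1))])
        fm = as_matrix(X)
        filtered, kept = variance_filter(fm)
        assert "f0003" not in kept
        assert filtered.shape == (10, 3)

    def test_identity_without_constants(self):
        fm = as_matrix(np.random.default_rng(1).normal(size=(10, 4)))
        filtered, kept = variance_filter(fm)
        assert kept == fm.feature_names

    def test_train_mask_applies_to_test(self):
        rng = np.random.default_rng(2)
        train = np.hstack([rng.normal(size=(10, 2)), np.zeros((10, 1))])
        _, kept = variance_filter(as_matrix(train))
        test = as_matrix(rng.normal(size=(4, 3)))
        cols = [test.feature_names.index(n) for n in kept]
        assert cols == [0, 1]

    def test_all_constant_error(self):
        with pytest.raises(ValueError):
            variance_filter(as_matrix(np.ones((5, 2))))


class TestAnovaFScores:
    def test_identical_class_means_zero(self):
        X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        y = np.array(["a"] * 3 + ["b"] * 3)
        assert anova_f_scores(X, y)[0] == pytest.approx(0.0)

    def test_hand_computed_instance(self):
        # (1,2,3) vs (7,8,9): between-SS 54 (df 1), within-SS 4 (df 4)
        X = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        y = np.array(["a"] * 3 + ["b"] * 3)
        F = anova_f_scores(X, y)[0]
        assert F == pytest.approx((54 / 1) / (4 / 4))
        # scipy as an independent oracle
        assert F == pytest.approx(stats.f_oneway(X[:3, 0], X[3:, 0]).statistic)

    def test_loop_oracle_random_matrix(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 8))
        y = rng.choice(["a", "b"], size=25)
        while min((y == "a").sum(), (y == "b").sum()) < 2:
            y = rng.choice(["a", "b"], size=25)
        F = anova_f_scores(X, y)
        for j in range(8):
            oracle = stats.f_oneway(X[y == "a", j], X[y == "b", j]).statistic
            assert F[j] == pytest.approx(oracle, abs=1e-9)

    def test_small_class_error(self):
        X = np.zeros((3, 1))
        with pytest.raises(ValueError):
            anova_f_scores(X, np.array(["a", "a", "b"]))


class TestSelectTopK:
    def test_k_equals_m(self):
        names = ("a", "b", "c")
        out = select_top_k(np.array([3.0, 1.0, 2.0]), names, 3)
        assert set(out) == set(names)

    def test_k_over_cap_error(self):
        names = tuple(f"f{i}" for i in range(300))
        with pytest.raises(ValueError):
            select_top_k(np.zeros(300), names, 201)

    def test_tie_break_lexicographic(self):
        names = ("zz", "aa", "mm")
        out = select_top_k(np.array([1.0, 1.0, 1.0]), names, 2)
        assert out == ("aa", "mm")


class TestGammaAndWeights:
    def test_gamma_formula(self):
        X = np.random.default_rng(0).normal(size=(50, 200))
        X = (X - X.mean()) / X.std()
        assert rbf_gamma(X) == pytest.approx(1 / (X.var() * 200))

    def test_gamma_unit_variance(self):
        X = np.array([[0.0, 2.0]] * 3 + [[2.0, 0.0]] * 3)  # pooled var 1
        assert X.var() == pytest.approx(1.0)
        assert rbf_gamma(X) == pytest.approx(0.5)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            rbf_gamma(np.ones((4, 3)))

    def test_balanced_weights_one(self):
        y = np.array(["a"] * 50 + ["b"] * 50)
        assert class_weights(y) == {"a": 1.0, "b": 1.0}

    def test_imbalanced_weights(self):
        y = np.array(["a"] * 20 + ["b"] * 40)
        w = class_weights(y)
        assert w["a"] == pytest.approx(1.5)
        assert w["b"] == pytest.approx(0.75)

    def test_three_equal_classes(self):
        y = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        assert all(v == pytest.approx(1.0) for v in class_weights(y).values())


class TestFitSvm:
    def test_separable_blobs_perfect_training_score(self):
        fm, y = blobs_matrix()
        model = fit_svm(fm, y, SvmConfig(k_grid=(5, 10), seed=4))
        pred = predict(model, fm)
        assert balanced_accuracy_score(y, pred) == 1.0

    def test_deterministic_choice(self):
        fm, y = blobs_matrix(seed=7)
        cfg = SvmConfig(k_grid=(5, 10), seed=1)
        m1, m2 = fit_svm(fm, y, cfg), fit_svm(fm, y, cfg)
        assert m1.chosen_params["k"] == m2.chosen_params["k"]
        assert m1.chosen_params["C"] == m2.chosen_params["C"]

    def test_default_c_grid_cardinality(self):
        assert len(SvmConfig().C_grid) == 3

    def test_one_class_error(self):
        fm, _ = blobs_matrix()
        with pytest.raises(ValueError):
            fit_svm(fm, np.array(["a"] * len(fm.sample_ids)))

    def test_selection_cap_200(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 1000)) + 0.0
        y = np.array(["a", "b"] * 20)
        X[y == "b"] += 0.5  # signal everywhere so large k is attractive
        model = fit_svm(as_matrix(X), y, SvmConfig(seed=0))
        assert len(model.selected_names) <= 200

    def test_no_test_leakage(self):
        fm, y = blobs_matrix()
        model = fit_svm(fm, y, SvmConfig(k_grid=(5,), seed=0))
        means_before = model.means.copy()
        test = as_matrix(np.random.default_rng(9).normal(size=(6, 10)) * 100)
        predict(model, test)
        assert np.array_equal(model.means, means_before)

    def test_save_load_prediction_equality(self, tmp_path):
        fm, y = blobs_matrix()
        model = fit_svm(fm, y, SvmConfig(k_grid=(5,), seed=0))
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        assert np.array_equal(predict(model, fm), predict(loaded, fm))


class TestFitFnn:
    def test_architecture(self):
        fm, y = blobs_matrix(n=40)
        model = fit_fnn(fm, y, FnnConfig(epochs=1, seed=0))
        net = model.model
        assert tuple(w.shape[1] for w in net.W) == (512, 256, 128, 1)

    def test_separable_training_accuracy(self):
        fm, y = blobs_matrix(n=40, sep=10.0)
        model = fit_fnn(fm, y, FnnConfig(seed=0))
        assert balanced_accuracy_score(y, predict(model, fm)) == 1.0

    def test_deterministic_given_seed(self):
        fm, y = blobs_matrix(n=40)
        cfg = FnnConfig(epochs=5, seed=3)
        p1 = predict(fit_fnn(fm, y, cfg), fm)
        p2 = predict(fit_fnn(fm, y, cfg), fm)
        assert np.array_equal(p1, p2)

    def test_non_binary_error(self):
        fm, _ = blobs_matrix(n=30)
        y = np.array(["a", "b", "c"] * 10)
        with pytest.raises(ValueError):
            fit_fnn(fm, y)

    def test_threshold_strictly_greater(self):
        fm, y = blobs_matrix(n=40)
        model = fit_fnn(fm, y, FnnConfig(epochs=1, seed=0))

        class FixedProba:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.full(len(X), self.p)

        model.model = FixedProba(0.6)
        assert (predict(model, fm) == model.classes[1]).all()
        model.model = FixedProba(0.5)  # exactly the threshold -> negative
        assert (predict(model, fm) == model.classes[0]).all()

    def test_batch_equals_per_sample(self):
        fm, y = blobs_matrix(n=40)
        model = fit_fnn(fm, y, FnnConfig(epochs=2, seed=0))
        batch = predict(model, fm)
        singles = [predict(model, fm.subset([s]))[0] for s in fm.sample_ids]
        assert list(batch) == singles

    def test_save_load_prediction_equality(self, tmp_path):
        fm, y = blobs_matrix(n=40)
        model = fit_fnn(fm, y, FnnConfig(epochs=3, seed=1))
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        assert np.array_equal(predict(model, fm), predict(loaded, fm))

    def test_missing_feature_columns_error(self):
        fm, y = blobs_matrix(n=40)
        model = fit_fnn(fm, y, FnnConfig(epochs=1, seed=0))
        partial = FeatureMatrix(
            fm.sample_ids, fm.feature_names[:5], fm.values[:, :5]
        )
        with pytest.raises(KeyError):
            predict(model, partial)
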