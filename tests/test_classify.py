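import numpy as np
import pandas as pd
import pytest

from methsubtypes.classify import (NBModel, assign_test_set, cross_validate,
                                   fit_nb, multiclass_auc, predict_nb,
                                   stratified_folds)


def _frame(values, features=None):
    values = np.asarray(values, float)
    features = features or [f"f{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=features)


class TestFitNB:
    def test_constant_classes_floor_variance(self):
        X = _frame([[0.0], [0.0], [1.0], [1.0]])
        model = fit_nb(X, [1, 1, 2, 2], var_floor=1e-6)
        assert model.means[:, 0] == pytest.approx([0.0, 1.0])
        assert model.variances[:, 0] == pytest.approx([1e-6, 1e-6])

    def test_hand_computed_moments(self):
        X = _frame([[0.1, 0.5], [0.3, 0.7], [0.8, 0.2], [0.6, 0.4]])
        model = fit_nb(X, ["a", "a", "b", "b"])
        assert model.priors == pytest.approx([0.5, 0.5])
        assert model.means[0] == pytest.approx([0.2, 0.6])
        assert model.means[1] == pytest.approx([0.7, 0.3])
        # ML variance (denominator n): ((0.1-0.2)^2 + (0.3-0.2)^2) / 2
        assert model.variances[0, 0] == pytest.approx(0.01)

    def test_class_with_one_sample_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_nb(_frame([[0.1], [0.2], [0.3]]), [1, 1, 2])

    def test_matches_sklearn_gaussian_nb(self, rng):
        from sklearn.naive_bayes import GaussianNB
        X = _frame(rng.normal(size=(60, 4)))
        y = rng.integers(0, 3, 60)
        model = fit_nb(X, y, var_floor=1e-12)
        _, post = predict_nb(model, X)
        ref = GaussianNB(var_smoothing=0.0).fit(X, y)
        assert np.allclose(post.to_numpy(), ref.predict_proba(X), atol=1e-8)


class TestPredictNB:
    def test_posterior_matches_brute_force_density_product(self):
        model = NBModel(classes=np.array([1, 2]),
                        priors=np.array([0.3, 0.7]),
                        means=np.array([[0.2, 0.5], [0.7, 0.1]]),
                        variances=np.array([[0.01, 0.04], [0.02, 0.03]]),
                        features=["f0", "f1"])
        x = np.array([0.4, 0.3])

        def dens(mu, var):
            return np.prod(np.exp(-(x - mu) ** 2 / (2 * var))
                           / np.sqrt(2 * np.pi * var))

        w = np.array([0.3 * dens(model.means[0], model.variances[0]),
                      0.7 * dens(model.means[1], model.variances[1])])
        expected = w / w.sum()
        _, post = predict_nb(model, _frame([x], ["f0", "f1"]))
        assert post.to_numpy()[0] == pytest.approx(expected, abs=1e-12)

    def test_posterior_rows_sum_to_one(self, rng):
        X = _frame(rng.uniform(size=(30, 5)))
        model = fit_nb(X, rng.integers(0, 3, 30))
        _, post = predict_nb(model, X)
        assert post.to_numpy().sum(axis=1) == pytest.approx(
            np.ones(30), abs=1e-12)

    def test_invariant_to_feature_order(self, rng):
        X = _frame(rng.uniform(size=(40, 4)))
        y = rng.integers(0, 2, 40)
        model = fit_nb(X, y)
        labels_a, post_a = predict_nb(model, X)
        shuffled = X[["f2", "f0", "f3", "f1"]]
        labels_b, post_b = predict_nb(model, shuffled)
        assert np.array_equal(labels_a, labels_b)
        assert np.allclose(post_a.to_numpy(), post_b.to_numpy())

    def test_missing_feature_named(self, rng):
        X = _frame(rng.uniform(size=(10, 2)))
        model = fit_nb(X, [1] * 5 + [2] * 5)
        with pytest.raises(KeyError, match="f1"):
            predict_nb(model, X[["f0"]])

    def test_well_separated_classes_confident(self, rng):
        X = np.vstack([rng.normal(0.1, 0.02, size=(20, 3)),
                       rng.normal(0.9, 0.02, size=(20, 3))])
        y = np.repeat([1, 2], 20)
        model = fit_nb(_frame(X), y)
        _, post = predict_nb(model, _frame(X))
        assert post.to_numpy()[np.arange(40), np.repeat([0, 1], 20)].min() \
            >= 0.99


class TestCrossValidate:
    def test_fold_assignment_spreads_small_classes(self):
        y = np.array([1] * 3 + [2] * 20)
        folds = stratified_folds(y, n_folds=10, seed=0)
        # the 3-sample class occupies 3 distinct folds
        assert len(set(folds[:3])) == 3

    def test_separable_data_perfect_accuracy(self, rng):
        X = _frame(np.vstack([rng.normal(0.1, 0.01, size=(30, 4)),
                              rng.normal(0.9, 0.01, size=(30, 4))]))
        y = np.repeat([1, 2], 30)
        cv = cross_validate(X, y, n_folds=10, seed=0)
        assert cv.accuracy == 1.0

    def test_deterministic_given_seed(self, rng):
        X = _frame(rng.uniform(size=(50, 3)))
        y = rng.integers(0, 2, 50)
        a = cross_validate(X, y, seed=3)
        b = cross_validate(X, y, seed=3)
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.folds, b.folds)
        assert np.array_equal(a.predictions, b.predictions)


class TestMulticlassAUC:
    def test_perfect_ranking_gives_one(self):
        post = pd.DataFrame({1: [0.9, 0.8, 0.1, 0.2],
                             2: [0.1, 0.2, 0.9, 0.8]})
        assert multiclass_auc(post, [1, 1, 2, 2]) == 1.0

    def test_two_class_equals_rank_sum_formula(self, rng):
        from scipy.stats import mannwhitneyu
        scores = rng.uniform(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        post = pd.DataFrame({0: 1 - scores, 1: scores})
        auc = multiclass_auc(post, y)
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        expected = u / ((y == 1).sum() * (y == 0).sum())
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_three_class_toy_matches_pairwise_counts(self):
        """6 samples, 3 classes: AUC equals the hand-averaged pairwise
        Mann-Whitney statistics."""
        post = pd.DataFrame({1: [0.7, 0.6, 0.2, 0.1, 0.1, 0.2],
                             2: [0.2, 0.3, 0.7, 0.8, 0.3, 0.2],
                             3: [0.1, 0.1, 0.1, 0.1, 0.6, 0.6]})
        y = [1, 1, 2, 2, 3, 3]
        # every pair ranks perfectly in both directions
        assert multiclass_auc(post, y) == 1.0
        # degrade pair (1,2): a class-1 sample now outranks class 2 on
        # the class-2 score column.  Hand count: A(1|2) stays 1.0;
        # A(2|1) = 2 winning pairs of 4 = 0.5; pair score 0.75.
        post.loc[0, 2] = 0.9
        expected = (0.75 + 1.0 + 1.0) / 3
        assert multiclass_auc(post, y) == pytest.approx(expected, abs=1e-12)

    def test_random_scores_near_half(self, rng):
        aucs = []
        for _ in range(200):
            post_raw = rng.uniform(size=(30, 3))
            post = pd.DataFrame(post_raw / post_raw.sum(axis=1)[:, None],
                                columns=[1, 2, 3])
            aucs.append(multiclass_auc(post, rng.integers(1, 4, 30)))
        assert abs(np.mean(aucs) - 0.5) < 0.02


class TestAssignTestSet:
    def test_test_equals_train_reproduces_in_sample_labels(
            self, default_cohort):
        m = default_cohort.methylation.iloc[:100]
        X = m.T
        y = default_cohort.true_labels
        model = fit_nb(X, y)
        in_sample, _ = predict_nb(model, X)
        assignment = assign_test_set(model, X, default_cohort.clinical,
                                     train_clinical=default_cohort.clinical,
                                     train_labels=in_sample)
        assert np.array_equal(assignment.labels.to_numpy(), in_sample)
        # identical membership on both sides: log-rank statistic is null
        assert all(r.statistic == pytest.approx(0.0, abs=1e-9)
                   for r in assignment.cross_set_logrank.values())
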