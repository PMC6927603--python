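import numpy as np
import pytest

from structsep.feature_table import FeatureMatrix
from structsep.mse_classifier import fit_mse, mse_rates, one_hot_targets, predict_mse


class TestFit:
    def test_closed_form_two_sample_problem(self):
        # x=0 in class 1, x=1 in class 2; augmented X = [[1,0],[1,1]], B = I.
        # X is invertible, so A = X^{-1} = [[1,0],[-1,1]].
        model = fit_mse(np.array([[0.0], [1.0]]), ["c1", "c2"])
        np.testing.assert_allclose(model.A, [[1.0, 0.0], [-1.0, 1.0]], atol=1e-12)
        assert predict_mse(model, [[0.0]]) == ["c1"]
        assert predict_mse(model, [[1.0]]) == ["c2"]

    def test_one_hot_targets_rows_sum_to_one(self):
        B = one_hot_targets(["a", "b", "a", "c"], ["a", "b", "c"])
        np.testing.assert_array_equal(B.sum(axis=1), np.ones(4))
        assert set(np.unique(B)) == {0.0, 1.0}

    def test_uniform_duplication_leaves_solution_unchanged(self, rng):
        X = rng.normal(size=(30, 4))
        labels = list(rng.choice(["a", "b", "c"], size=30))
        base = fit_mse(X, labels)
        doubled = fit_mse(np.vstack([X, X]), labels + labels)
        np.testing.assert_allclose(base.A, doubled.A, atol=1e-10)

    def test_matches_dense_least_squares_oracle(self, rng):
        for _ in range(10):
            X = rng.normal(size=(60, 2))
            labels = list(rng.choice(["a", "b", "c"], size=60))
            model = fit_mse(X, labels)
            aug = np.hstack([np.ones((60, 1)), X])
            B = one_hot_targets(labels, model.class_order)
            expected, *_ = np.linalg.lstsq(aug, B, rcond=None)
            np.testing.assert_allclose(model.A, expected, atol=1e-8)

    def test_rank_deficient_features_handled(self, rng):
        # duplicated column => collinear design; SVD pseudo-inverse must cope
        x = rng.normal(size=(40, 1))
        X = np.hstack([x, x, rng.normal(size=(40, 1))])
        labels = list(rng.choice(["a", "b"], size=40))
        model = fit_mse(X, labels)
        assert np.all(np.isfinite(model.A))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_mse(np.zeros((3, 2)), ["a", "a", "a"])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fit_mse(np.array([[np.inf], [0.0]]), ["a", "b"])

    def test_residual_optimality_against_perturbations(self, rng):
        X = rng.normal(size=(25, 3))
        labels = list(rng.choice(["a", "b", "c"], size=25))
        model = fit_mse(X, labels)
        aug = np.hstack([np.ones((25, 1)), X])
        B = one_hot_targets(labels, model.class_order)
        best = np.trace((aug @ model.A - B).T @ (aug @ model.A - B))
        for _ in range(20):
            other = model.A + rng.normal(scale=0.1, size=model.A.shape)
            alt = np.trace((aug @ other - B).T @ (aug @ other - B))
            assert best <= alt + 1e-10


class TestPredict:
    def test_tie_breaks_to_earliest_class_and_logs(self, caplog):
        # symmetric discriminants: both classes score identically at x = 0
        from structsep.mse_classifier import MSEModel

        model = MSEModel(np.array([[0.5, 0.5], [-1.0, 1.0]]), ["c1", "c2"])
        with caplog.at_level("INFO"):
            assert predict_mse(model, [[0.0]]) == ["c1"]
        assert "tie" in caplog.text

    def test_dimension_mismatch_rejected(self):
        model = fit_mse(np.array([[0.0], [1.0]]), ["a", "b"])
        with pytest.raises(ValueError, match="1-dim"):
            predict_mse(model, [[0.0, 1.0]])

    def test_output_is_always_a_known_class(self, rng):
        X = rng.normal(size=(30, 3))
        labels = list(rng.choice(["a", "b", "c"], size=30))
        model = fit_mse(X, labels)
        for pred in predict_mse(model, rng.normal(size=(50, 3))):
            assert pred in model.class_order

    def test_affine_invariance_of_predictions(self, rng):
        X = rng.normal(size=(40, 3))
        labels = list(rng.choice(["a", "b", "c"], size=40))
        queries = rng.normal(size=(30, 3))
        base = predict_mse(fit_mse(X, labels), queries)
        for _ in range(5):
            M = rng.normal(size=(3, 3))
            M += 3 * np.eye(3)  # keep it comfortably invertible
            t = rng.normal(size=3)
            mapped = predict_mse(fit_mse(X @ M + t, labels), queries @ M + t)
            assert mapped == base


class TestRates:
    def test_perfectly_separated_blobs_are_100_percent(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(20, 2)), rng.normal(10, 0.1, size=(20, 2))])
        labels = ["a"] * 20 + ["b"] * 20
        model = fit_mse(X, labels)
        table = mse_rates(model, X, labels)
        assert [r.rate_percent for r in table.rates] == [100.0, 100.0]
        assert table.confusion[("a", "a")] == 20

    def test_rates_use_feature_matrix_labels(self, rng):
        fm = FeatureMatrix.from_array(
            np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))]),
            ids=[f"p{i}" for i in range(20)],
            columns=["x", "y"],
            labels=["a"] * 10 + ["b"] * 10,
        )
        table = mse_rates(fit_mse(fm), fm)
        assert all(r.denominator == 10 for r in table.rates)

    def test_rates_are_deterministic(self, rng):
        X = rng.normal(size=(60, 4))
        labels = list(rng.choice(["a", "b", "c"], size=60))
        t1 = mse_rates(fit_mse(X, labels), X, labels)
        t2 = mse_rates(fit_mse(X, labels), X, labels)
        assert [(r.numerator, r.denominator) for r in t1.rates] == [
            (r.numerator, r.denominator) for r in t2.rates
        ]


class TestCrossValidation:
    def test_cv_on_separable_blobs_stays_high(self, rng):
        from structsep.mse_classifier import mse_cv_rates

        X = np.vstack([rng.normal(0, 0.3, (30, 2)), rng.normal(10, 0.3, (30, 2))])
        labels = ["a"] * 30 + ["b"] * 30
        table = mse_cv_rates(X, labels, k=5, seed=1)
        assert all(r.rate_percent >= 90.0 for r in table.rates)
        assert table.classifier == "mse-cv"

    def test_cv_is_seed_deterministic(self, rng):
        from structsep.mse_classifier import mse_cv_rates

        X = rng.normal(size=(60, 3))
        labels = list(rng.choice(["a", "b"], size=60))
        t1 = mse_cv_rates(X, labels, k=4, seed=9)
        t2 = mse_cv_rates(X, labels, k=4, seed=9)
        assert [(r.numerator, r.denominator) for r in t1.rates] == [
            (r.numerator, r.denominator) for r in t2.rates
        ]

    def test_bad_fold_count_rejected(self, rng):
        from structsep.mse_classifier import mse_cv_rates

        with pytest.raises(ValueError):
            mse_cv_rates(rng.normal(size=(6, 2)), ["a", "b"] * 3, k=1)
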