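"""LogitBoost, feature variants, LOOCV, and confusion-matrix metrics."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metabophen as mp
from metabophen.classify import Stump, clopper_pearson, _fit_stump
from metabophen.containers import ValidationError


def _xy(rng, n_per=10, p=3, sep=3.0):
    """Two separable Gaussian classes."""
    x = np.vstack([
        rng.normal(0, 1, (n_per, p)),
        rng.normal(sep, 1, (n_per, p)),
    ])
    X = pd.DataFrame(x, index=[f"S{i}" for i in range(2 * n_per)])
    y = pd.Series(["ASD_DD"] * n_per + ["CANCER"] * n_per, index=X.index)
    return X, y


class TestStump:
    def test_weighted_least_squares_optimum(self, rng):
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        z = np.array([-1.0, -1.0, 1.0, 1.0])
        w = np.ones(4)
        st_ = _fit_stump(x, z, w)
        assert st_.threshold == pytest.approx(1.5)
        assert st_.left_value == pytest.approx(-1.0)
        assert st_.right_value == pytest.approx(1.0)

    def test_constant_features_fall_back_to_intercept(self):
        st_ = _fit_stump(np.ones((4, 2)), np.array([1.0, 2.0, 3.0, 4.0]),
                         np.ones(4))
        assert st_.left_value == st_.right_value == pytest.approx(2.5)


class TestLogitBoost:
    def test_separable_training_accuracy_one(self, rng):
        X, y = _xy(rng, p=1)
        model = mp.fit_logitboost(X, y, n_iter=10)
        assert (model.predict(X.to_numpy()) == y.to_numpy()).all()

    def test_binary_committee_antisymmetric(self, rng):
        X, y = _xy(rng)
        model = mp.fit_logitboost(X, y, n_iter=5)
        s = model.scores(X.to_numpy())
        assert np.allclose(s[:, 0], -s[:, 1])

    def test_multiclass_one_vs_rest(self, rng):
        x = np.vstack([rng.normal(c * 4, 1, (8, 2)) for c in range(3)])
        X = pd.DataFrame(x, index=[f"S{i}" for i in range(24)])
        y = pd.Series(["A"] * 8 + ["B"] * 8 + ["C"] * 8, index=X.index)
        model = mp.fit_logitboost(X, y, n_iter=15)
        assert len(model.committees) == 3
        assert (model.predict(X.to_numpy()) == y.to_numpy()).all()

    def test_single_class_rejected(self, rng):
        X, _ = _xy(rng)
        with pytest.raises(ValidationError):
            mp.fit_logitboost(X, pd.Series(["A"] * len(X), index=X.index), 5)


class TestRemoveLinearCorrelated:
    def test_duplicate_column_removed(self, rng):
        a = rng.normal(size=20)
        X = pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=20)})
        out = mp.remove_linear_correlated(X)
        assert out.shape[1] == 2

    def test_exact_linear_combination_removed_rank_preserved(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        X = pd.DataFrame({"a": a, "b": b, "c": a + b})
        out = mp.remove_linear_correlated(X)
        assert out.shape[1] == 2
        assert np.linalg.matrix_rank(out.to_numpy()) == np.linalg.matrix_rank(
            X.to_numpy()
        )

    def test_high_correlation_pruned(self, rng):
        a = rng.normal(size=200)
        X = pd.DataFrame({
            "a": a,
            "b": a + rng.normal(0, 0.1, 200),  # r ~ 0.995
            "c": rng.normal(size=200),
        })
        out = mp.remove_linear_correlated(X, corr_threshold=0.9)
        assert out.shape[1] == 2 and "c" in out.columns

    def test_independent_columns_untouched(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 6)))
        out = mp.remove_linear_correlated(X, corr_threshold=0.9)
        assert out.shape[1] == 6

    def test_never_increases_feature_count(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 30)))
        assert mp.remove_linear_correlated(X).shape[1] <= 30


class TestPCAReduce:
    def test_collinear_two_features_one_component(self, rng):
        a = rng.normal(size=20)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        red = mp.pca_reduce(X, 0.95)
        assert red.n_components == 1

    def test_isotropic_needs_most_components(self):
        keeps = []
        for seed in range(5):
            X = pd.DataFrame(np.random.default_rng(seed).normal(size=(200, 5)))
            keeps.append(mp.pca_reduce(X, 0.95).n_components)
        assert min(keeps) >= 4

    def test_scores_uncorrelated(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 6)))
        red = mp.pca_reduce(X, 1.0)
        cov = np.cov(red.scores.to_numpy().T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-9

    def test_component_cap(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 50)))
        assert mp.pca_reduce(X, 1.0).n_components <= 9


class TestLoocv:
    def test_each_prediction_from_unseen_sample(self, rng):
        X, y = _xy(rng)
        res = mp.loocv(X, y, iter_grid=(5,))
        assert len(res.predictions) == len(X)
        assert list(res.predictions.index) == list(X.index)

    def test_separable_accuracy_one(self, rng):
        X, y = _xy(rng, sep=5.0)
        for variant in ("ALL_SIG", "REMOVE_LINEAR_CORRELATED", "PCA"):
            res = mp.loocv(X, y, variant=variant, iter_grid=(11,))
            assert res.accuracy == 1.0

    def test_order_invariance(self, rng):
        X, y = _xy(rng, sep=1.0)
        res = mp.loocv(X, y, iter_grid=(5,))
        perm = rng.permutation(len(X))
        res_p = mp.loocv(X.iloc[perm], y.iloc[perm], iter_grid=(5,))
        assert (res.predictions.loc[X.index] == res_p.predictions.loc[X.index]).all()

    def test_nested_pca_runs(self, rng):
        X, y = _xy(rng, sep=5.0)
        res = mp.loocv(X, y, variant="PCA", iter_grid=(5,), nested=True)
        assert res.accuracy > 0.9

    def test_iteration_grid_tie_breaks_to_smallest(self, rng):
        X, y = _xy(rng, sep=5.0)
        res = mp.loocv(X, y, iter_grid=(11, 21))
        assert res.n_iter == 11  # both reach accuracy 1.0


class TestConfusionReport:
    def _series(self, truth, pred):
        idx = [f"S{i}" for i in range(len(truth))]
        return pd.Series(pred, index=idx), pd.Series(truth, index=idx)

    def test_table_one_arithmetic(self):
        """TP=9 FN=1 TN=10 FP=0 (positive cancer) -> 0.95 / 0.90 / 1.00."""
        truth = ["CANCER"] * 10 + ["ASD_DD"] * 10
        pred = ["CANCER"] * 9 + ["ASD_DD"] + ["ASD_DD"] * 10
        rep = mp.confusion_report(*self._series(truth, pred))
        assert rep.accuracy == pytest.approx(0.95)
        assert rep.sensitivity == pytest.approx(0.90)
        assert rep.specificity == pytest.approx(1.00)
        assert rep.nir == pytest.approx(0.5)

    def test_clopper_pearson_all_correct(self):
        low, high = clopper_pearson(20, 20)
        assert low == pytest.approx(0.8316, abs=2e-4)
        assert high == 1.0

    def test_clopper_pearson_matches_inversion_oracle(self):
        """CI bounds invert the exact binomial test."""
        for k, n in [(5, 20), (19, 20), (0, 7), (10, 30)]:
            low, high = clopper_pearson(k, n)
            if 0 < k:
                assert stats.binom.sf(k - 1, n, low) == pytest.approx(0.025, abs=1e-9)
            if k < n:
                assert stats.binom.cdf(k, n, high) == pytest.approx(0.025, abs=1e-9)

    def test_nir_binomial_tail(self):
        truth = ["CANCER"] * 10 + ["ASD_DD"] * 10
        pred = ["CANCER"] * 10 + ["ASD_DD"] * 9 + ["CANCER"]
        rep = mp.confusion_report(*self._series(truth, pred))
        assert rep.p_vs_nir == pytest.approx(21 * 0.5**20, rel=1e-9)

    def test_metrics_recomputable_from_confusion(self, rng):
        X, y = _xy(rng, sep=1.0)
        res = mp.loocv(X, y, iter_grid=(11,))
        rep = mp.confusion_report(res.predictions, y)
        cm = rep.confusion.to_numpy()
        assert rep.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        tp = rep.confusion.loc["CANCER", "CANCER"]
        fn = rep.confusion.loc["CANCER"].sum() - tp
        assert rep.sensitivity == pytest.approx(tp / (tp + fn))

    def test_three_group_per_class_metrics(self):
        truth = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        pred = ["A"] * 4 + ["B"] * 3 + ["A"] + ["C"] * 4
        rep = mp.confusion_report(*self._series(truth, pred), positive_class="A")
        assert isinstance(rep.sensitivity, dict)
        assert rep.sensitivity["B"] == pytest.approx(0.75)
        assert rep.specificity["A"] == pytest.approx(7 / 8)


class TestPerformanceGrid:
    def test_cartesian_row_count_and_empty_handling(self, cohort, rng):
        ids2 = [s for s in cohort.sample_ids
                if cohort.frame.loc[s, "group"] in ("ASD_DD", "CANCER")]
        X2 = pd.DataFrame(rng.normal(size=(20, 3)), index=ids2)
        X2.iloc[:10] += 4.0  # separable by group
        empty = pd.DataFrame(index=ids2)
        feature_sets = {
            "CELLS": {"two_group": X2, "three_group": empty},
            "MEDIA": {"two_group": empty, "three_group": empty},
        }
        grid, reports = mp.performance_grid(feature_sets, cohort, iter_grid=(5,))
        assert len(grid) == 12
        filled = grid[grid["n_features"] > 0]
        assert (filled["source_matrix"] == "CELLS").all()
        assert filled["accuracy"].min() >= 0.9
        na_rows = grid[grid["n_features"] == 0]
        assert na_rows["accuracy"].isna().all()
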