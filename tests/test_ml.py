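"""Nested-CV SVM protocol tests: rescaling, subset enumeration, confusion
metrics, AUC oracle, separable/null classification and regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphacoupling import (
    ALL_FEATURES,
    BEHAVIORAL_FEATURES,
    EEG_FEATURES,
    candidate_subsets,
    confusion_metrics,
    nested_cv_classify,
    nested_cv_regress,
    rescale01,
    roc_auc,
)

SMALL_C = (1.0, 32.0)
SMALL_G = (0.125, 2.0)


def test_feature_registry():
    assert len(ALL_FEATURES) == 15
    assert len(BEHAVIORAL_FEATURES) == 6
    assert len(EEG_FEATURES) == 9
    assert set(BEHAVIORAL_FEATURES).isdisjoint(EEG_FEATURES)


class TestRescale01:
    def test_simple_mapping(self):
        out, _ = rescale01(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_extrapolation_beyond_unit(self):
        out, sc = rescale01(np.array([[0.0], [10.0], [15.0]]), fit_rows=[0, 1])
        assert out[2, 0] == pytest.approx(1.5)

    def test_idempotent_on_spanning_feature(self):
        x = np.array([[0.0], [0.25], [1.0]])
        out, _ = rescale01(x)
        np.testing.assert_allclose(out, x)

    def test_constant_feature_raises(self):
        with pytest.raises(ValueError, match="constant"):
            rescale01(np.array([[1.0, 2.0], [1.0, 3.0]]))

    def test_dataframe_round_trip(self):
        df = pd.DataFrame({"a": [1.0, 3.0], "b": [0.0, 2.0]})
        out, _ = rescale01(df)
        assert list(out.columns) == ["a", "b"]


def test_candidate_subsets_counts():
    subs = candidate_subsets(4, max_size=2)
    assert len(subs) == 4 + 6
    assert all(len(s) <= 2 for s in subs)
    assert len(candidate_subsets(3)) == 7  # all non-empty subsets
    with pytest.raises(ValueError):
        candidate_subsets(0)


class TestConfusionMetrics:
    def test_handworked_counts(self):
        m = confusion_metrics(tp=9, fp=2, fn=1, tn=8)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(9 / 11)
        assert m["npv"] == pytest.approx(8 / 9)
        assert m["accuracy"] == pytest.approx(0.85)

    def test_perfect_classifier(self):
        m = confusion_metrics(tp=5, fp=0, fn=0, tn=5)
        assert all(v == 1.0 for v in m.values())

    def test_undefined_rates_are_nan_not_zero(self):
        m = confusion_metrics(tp=0, fp=3, fn=0, tn=7)
        assert np.isnan(m["sensitivity"])
        assert not np.isnan(m["specificity"])

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_arithmetic_identities(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = confusion_metrics(tp, fp, fn, tn)
        total = tp + fp + fn + tn
        assert m["accuracy"] == pytest.approx((tp + tn) / total)
        for v in m.values():
            assert np.isnan(v) or 0.0 <= v <= 1.0


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_matches_pair_counting_oracle_with_ties(self):
        scores = np.array([0.1, 0.4, 0.4, 0.6, 0.7, 0.4])
        labels = np.array([0, 0, 1, 1, 1, 0])
        wins = 0.0
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        for p in pos:
            for q in neg:
                wins += 1.0 if p > q else (0.5 if p == q else 0.0)
        assert roc_auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(base)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


def separable_data(n=24, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    X[y == "B", 0] += 10.0  # disjoint support on feature 0
    return X, y


class TestNestedCvClassify:
    def test_separable_near_perfect(self):
        X, y = separable_data()
        rep = nested_cv_classify(
            X, y, c_grid=SMALL_C, g_grid=SMALL_G, max_subset_size=1,
            k=4, reps=3, seed=0,
        )
        assert rep.summary.loc["accuracy", "mean"] >= 0.99
        assert rep.summary.loc["auc", "mean"] >= 0.99

    def test_reproducible_given_seed(self):
        X, y = separable_data(seed=1)
        a = nested_cv_classify(X, y, c_grid=SMALL_C, g_grid=SMALL_G,
                               max_subset_size=1, k=4, reps=2, seed=7)
        b = nested_cv_classify(X, y, c_grid=SMALL_C, g_grid=SMALL_G,
                               max_subset_size=1, k=4, reps=2, seed=7)
        pd.testing.assert_frame_equal(a.per_rep, b.per_rep)
        assert a.selections == b.selections

    def test_informative_feature_selected(self):
        """When only one feature separates the classes, the inner selection
        picks it in the majority of outer folds."""
        X, y = separable_data(seed=2)
        rep = nested_cv_classify(X, y, c_grid=SMALL_C, g_grid=SMALL_G,
                                 max_subset_size=1, k=4, reps=3, seed=3)
        hits = sum(1 for s in rep.selections if 0 in s["subset"])
        assert hits / len(rep.selections) > 0.5

    def test_per_rep_confusion_identities(self):
        X, y = separable_data(seed=3)
        X[:, 0] = np.random.default_rng(4).normal(size=len(y))  # make it hard
        rep = nested_cv_classify(X, y, c_grid=SMALL_C, g_grid=SMALL_G,
                                 max_subset_size=1, k=4, reps=3, seed=5)
        for _, r in rep.per_rep.iterrows():
            tp, fp, fn, tn = r["tp"], r["fp"], r["fn"], r["tn"]
            assert tp + fp + fn + tn == len(y)
            assert r["accuracy"] == pytest.approx((tp + tn) / len(y))
            if tp + fn > 0:
                assert r["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp > 0:
                assert r["specificity"] == pytest.approx(tn / (tn + fp))

    def test_leak_flag_changes_scaling_and_uses_heldout_rows(self):
        """Mechanism check: with an extreme value confined to one fold, the
        leaky variant's rescaling provably depends on held-out rows, so the
        two variants give different pooled decision scores."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 2))
        X[0, 0] = 1e4  # outlier that dominates the global range
        y = np.array(["A", "B"] * 6)
        strict = nested_cv_classify(X, y, c_grid=(1.0,), g_grid=(0.5,),
                                    max_subset_size=2, k=3, reps=1, seed=0)
        leaky = nested_cv_classify(X, y, c_grid=(1.0,), g_grid=(0.5,),
                                   max_subset_size=2, k=3, reps=1, seed=0,
                                   leak_rescale=True)
        assert not strict.per_rep.equals(leaky.per_rep) or (
            strict.selections != leaky.selections
        )

    def test_class_size_guard(self):
        X, y = separable_data(n=10)
        with pytest.raises(ValueError, match="per class"):
            nested_cv_classify(X, y, k=10)


class TestNestedCvRegress:
    def test_linear_target_recovered(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        t = 2.0 * X[:, 1] + 0.05 * rng.normal(size=30)
        rep = nested_cv_regress(X, t, c_grid=(8.0, 128.0), g_grid=(0.5, 4.0),
                                max_subset_size=1, k=5, reps=2, seed=0)
        assert rep.summary.loc["r2", "mean"] >= 0.9

    def test_null_target_low_r2(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        t = rng.normal(size=30)
        rep = nested_cv_regress(X, t, c_grid=SMALL_C, g_grid=SMALL_G,
                                max_subset_size=1, k=5, reps=4, seed=1)
        assert rep.summary.loc["r2", "mean"] < 0.2
        assert rep.summary.loc["mse", "mean"] >= 0.0

    def test_constant_target_raises(self):
        with pytest.raises(ValueError, match="constant target"):
            nested_cv_regress(np.random.default_rng(9).normal(size=(20, 2)),
                              np.ones(20))

    def test_mean_predictor_mse_equals_variance(self):
        """Baseline sanity: predicting the mean of a target gives MSE equal
        to its population variance."""
        rng = np.random.default_rng(10)
        t = rng.normal(size=2000)
        mse = np.mean((t - t.mean()) ** 2)
        assert mse == pytest.approx(np.var(t))


def test_ci_is_percentile_over_reps():
    X, y = separable_data(seed=11)
    rep = nested_cv_classify(X, y, c_grid=SMALL_C, g_grid=SMALL_G,
                             max_subset_size=1, k=4, reps=5, seed=2)
    accs = rep.per_rep["accuracy"].to_numpy()
    assert rep.summary.loc["accuracy", "ci_lo"] == pytest.approx(
        np.percentile(accs, 2.5)
    )
    assert rep.summary.loc["accuracy", "ci_hi"] == pytest.approx(
        np.percentile(accs, 97.5)
    )
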