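"""Windowing, feature extraction, forward selection and LDA evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import cross_val_score

from dmama import (
    FeatureTable,
    ShrunkLda,
    extract_features,
    extract_window,
    feature_names,
    forward_select,
    optimize_window,
    train_eval_lda,
)
from dmama.classify import CHANNELS, WINDOW_CANDIDATES_MS, _cv_error


class TestExtractWindow:
    grid = np.arange(0, 10, 0.01)  # 100 Hz

    def channels(self):
        return np.arange(len(self.grid) * 9, dtype=float).reshape(-1, 9)

    def test_300ms_window_has_31_samples(self):
        win = extract_window(self.grid, self.channels(), 5.0, 300.0)
        assert win.shape == (31, 9)

    def test_window_ends_at_toe_off_sample(self):
        win = extract_window(self.grid, self.channels(), 5.0, 300.0)
        idx = int(np.searchsorted(self.grid, 5.0 + 1e-9, "right")) - 1
        assert np.array_equal(win[-1], self.channels()[idx])

    def test_full_stance_window_starts_at_heel_strike(self):
        # stance [4.4, 5.0]: a 600 ms window reaches back to heel strike
        win = extract_window(self.grid, self.channels(), 5.0, 600.0)
        assert np.array_equal(win[0], self.channels()[440])

    def test_equal_length_across_strides(self):
        w1 = extract_window(self.grid, self.channels(), 3.123, 300.0)
        w2 = extract_window(self.grid, self.channels(), 7.891, 300.0)
        assert w1.shape == w2.shape

    def test_window_before_start_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            assert extract_window(self.grid, self.channels(), 0.1, 300.0) is None


class TestExtractFeatures:
    def test_constant_channels(self):
        win = np.full((10, 9), 4.2)
        f = extract_features(win)
        names = feature_names()
        by = dict(zip(names, f))
        for ch in CHANNELS:
            assert by[f"{ch}_mean"] == pytest.approx(4.2)
            assert by[f"{ch}_min"] == by[f"{ch}_max"] == 4.2
            assert by[f"{ch}_start"] == by[f"{ch}_end"] == 4.2
            assert by[f"{ch}_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_values(self):
        win = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 9))
        by = dict(zip(feature_names(), extract_features(win)))
        assert by["fx_mean"] == 2.0
        assert by["fx_sd"] == pytest.approx(1.0)  # sample (n-1) formula
        assert by["fx_min"] == 1.0 and by["fx_max"] == 3.0
        assert by["fx_start"] == 1.0 and by["fx_end"] == 3.0

    def test_feature_count_is_54(self, rng):
        assert extract_features(rng.normal(size=(31, 9))).shape == (54,)
        assert len(feature_names()) == 54

    def test_single_sample_window_sd_zero(self):
        f = extract_features(np.ones((1, 9)))
        assert dict(zip(feature_names(), f))["my_sd"] == 0.0

    def test_position_invariance(self, rng):
        win = rng.normal(size=(31, 9))
        assert np.array_equal(extract_features(win), extract_features(win.copy()))


def synthetic_table(rng, n_per_class=40, n_classes=2, n_features=10, sep_col=0,
                    sep=6.0, classes=None):
    """Gaussian feature table with one separating column among noise."""
    classes = classes or [f"c{i}" for i in range(n_classes)]
    X, y = [], []
    for i, c in enumerate(classes):
        block = rng.standard_normal((n_per_class, n_features))
        block[:, sep_col] += sep * i
        X.append(block)
        y += [c] * n_per_class
    X = pd.DataFrame(np.vstack(X), columns=[f"f{j}" for j in range(n_features)])
    n = len(X)
    return FeatureTable(
        X=X,
        y=pd.Series(y, name="mode"),
        subject=pd.Series(np.zeros(n, dtype=int), name="subject"),
        stiffness=pd.Series(np.zeros(n, dtype=int), name="stiffness_code"),
    )


class TestForwardSelect:
    def test_planted_feature_found_first(self, rng):
        table = synthetic_table(rng, sep_col=3)
        selected = forward_select(table, folds=5, seed=0)
        assert selected[0] == "f3"
        # exhaustive single-feature oracle via scikit-learn LDA
        scores = {
            col: cross_val_score(
                LinearDiscriminantAnalysis(), table.X[[col]], table.y, cv=5
            ).mean()
            for col in table.X.columns
        }
        assert max(scores, key=scores.get) == "f3"

    def test_identical_features_tie_breaks_to_first(self, rng):
        base = rng.standard_normal(60) + np.repeat([0.0, 5.0], 30)
        X = pd.DataFrame({f"f{j}": base for j in range(6)})
        table = FeatureTable(
            X=X,
            y=pd.Series(np.repeat(["a", "b"], 30)),
            subject=pd.Series(np.zeros(60, dtype=int)),
            stiffness=pd.Series(np.zeros(60, dtype=int)),
        )
        selected = forward_select(table, folds=5, seed=0)
        assert selected == ["f0"]

    def test_cv_error_non_increasing_along_selection(self, rng):
        table = synthetic_table(rng, n_per_class=30, n_classes=3, n_features=8,
                                sep=1.2, sep_col=2)
        selected = forward_select(table, folds=5, seed=0)
        assert selected  # separable-ish data selects something
        errs = [
            _cv_error(table, selected[: k + 1], 5, 0, 0.01)
            for k in range(len(selected))
        ]
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_single_class_rejected(self, rng):
        table = synthetic_table(rng, n_classes=1)
        with pytest.raises(ValueError):
            forward_select(table, folds=5, seed=0)

    def test_deterministic_given_seed(self, rng):
        table = synthetic_table(rng, n_classes=3, sep=1.5)
        a = forward_select(table, folds=5, seed=3)
        b = forward_select(table, folds=5, seed=3)
        assert a == b


class TestOptimizeWindow:
    def test_candidate_grid_arithmetic(self):
        assert list(WINDOW_CANDIDATES_MS) == [
            100, 133, 166, 199, 232, 265, 298, 331, 364, 397, 430, 463, 496
        ]
        assert len(WINDOW_CANDIDATES_MS) == 13

    def test_single_candidate_returned(self, rng):
        table = synthetic_table(rng)
        best, errs = optimize_window(lambda w: table, ["f0"], candidates=[250],
                                     folds=5, seed=0)
        assert best == 250 and set(errs) == {250}

    def test_flat_error_curve_smallest_window(self, rng):
        table = synthetic_table(rng)  # perfectly separable: error 0 everywhere
        best, errs = optimize_window(lambda w: table, ["f0"],
                                     candidates=[300, 100, 200], folds=5, seed=0)
        assert best == 100
        assert len(set(errs.values())) == 1

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            optimize_window(lambda w: synthetic_table(rng), ["f0"], candidates=[])


class TestShrunkLda:
    def test_matches_sklearn_lda_unshrunk(self, rng):
        X = rng.standard_normal((200, 5))
        y = np.repeat(["a", "b", "c"], [70, 70, 60])
        X[y == "b"] += [2, 0, 0, 0, 1]
        X[y == "c"] += [0, 2, 1, 0, 0]
        ours = ShrunkLda(shrinkage=0.0).fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        Xt = rng.standard_normal((100, 5))
        assert np.array_equal(ours.predict(Xt), ref.predict(Xt))

    def test_singular_covariance_survives(self):
        X = np.zeros((20, 3))
        X[10:, 0] = 1.0  # two point-mass classes, zero within-class scatter
        y = np.repeat(["a", "b"], 10)
        model = ShrunkLda(shrinkage=0.0).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_sklearn_get_set_params(self):
        m = ShrunkLda(shrinkage=0.1)
        assert m.get_params() == {"shrinkage": 0.1}
        m.set_params(shrinkage=0.0)
        assert m.shrinkage == 0.0


class TestTrainEvalLda:
    def test_separable_gaussians_perfect_accuracy(self, rng):
        table = synthetic_table(rng, n_per_class=100, n_classes=2, sep=8.0)
        report = train_eval_lda(table, folds=10, seed=0)
        assert report.overall_accuracy == 100.0

    def test_permuted_balanced_labels_near_chance(self, rng):
        table = synthetic_table(rng, n_per_class=60, n_classes=5, sep=8.0)
        permuted = FeatureTable(
            X=table.X,
            y=pd.Series(rng.permutation(table.y.to_numpy()), name="mode"),
            subject=table.subject,
            stiffness=table.stiffness,
        )
        report = train_eval_lda(permuted, folds=10, seed=0)
        n = len(permuted)
        lo = binom.ppf(0.005, n, 0.2) / n * 100
        hi = binom.ppf(0.995, n, 0.2) / n * 100
        assert lo <= report.overall_accuracy <= hi

    def test_confusion_bookkeeping(self, rng):
        table = synthetic_table(rng, n_per_class=30, n_classes=3, sep=1.0)
        report = train_eval_lda(table, folds=5, seed=0)
        cm = report.confusion.to_numpy()
        assert cm.sum() == report.n_strides
        assert report.overall_accuracy == pytest.approx(
            100.0 * np.trace(cm) / cm.sum()
        )
        # row sums equal per-class stride counts
        assert np.array_equal(cm.sum(axis=1), table.y.value_counts().sort_index().to_numpy())

    def test_small_class_reduces_folds_with_warning(self, rng):
        table = synthetic_table(rng, n_per_class=4, n_classes=2, sep=8.0)
        with pytest.warns(UserWarning, match="folds reduced"):
            train_eval_lda(table, folds=10, seed=0)

    def test_bit_reproducible_given_seed(self, rng):
        table = synthetic_table(rng, n_per_class=30, n_classes=3, sep=1.0)
        a = train_eval_lda(table, folds=5, seed=9)
        b = train_eval_lda(table, folds=5, seed=9)
        assert a.confusion.equals(b.confusion)
        assert a.overall_accuracy == b.overall_accuracy


class TestOnSyntheticSessions:
    def test_default_sessions_classify_above_90pct(self, default_streams):
        """Paper-like imbalance, per-(subject, stiffness) models, 10-fold CV."""
        from dmama import build_feature_table

        table = build_feature_table(default_streams, 300.0)
        report = train_eval_lda(table, folds=10, seed=0)
        assert report.overall_accuracy > 90.0
        assert report.confusion.shape == (5, 5)
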