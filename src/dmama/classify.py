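"""Locomotion-mode classification from load-cell-derived channels only.

Nine channels are available per stride once the wrench is in the shank
frame: the six sensed components (Fx, Fy, Fz, Mx, My, Mz), the derived
ankle and knee moments, and the sagittal force magnitude.  Streams are
resampled to 100 Hz; from a fixed-length window ending at toe-off, six
statistics per channel (mean, SD, min, max, starting value, ending value)
give 54 features per stride.  Greedy forward selection under cross-
validated misclassification error prunes the feature set, the window
length is optimized over 100-500 ms in 33 ms steps, and the final model is
a pooled-covariance linear discriminant analysis fitted per (subject,
stiffness) group — stiffness is known to a semi-active controller, so each
stiffness setting gets its own model — and scored by stratified k-fold
cross-validation with an aggregated confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .metric import joint_moments
from .series import StrideSegment, SubjectGeometry, WrenchSeries
from .strides import resample_uniform, sagittal_force_magnitude

CHANNELS = ("fx", "fy", "fz", "mx", "my", "mz", "m_ankle", "m_knee", "f_sag")
STATISTICS = ("mean", "sd", "min", "max", "start", "end")

RESAMPLE_RATE_HZ = 100.0
#: candidate window lengths, ms (100-500 in 33 ms increments)
WINDOW_CANDIDATES_MS = tuple(range(100, 501, 33))
DEFAULT_WINDOW_MS = 300.0
SHRINKAGE_GRID = (0.0, 0.01, 0.1)


def feature_names() -> list[str]:
    """The fixed 54-feature column order: channel-major, statistic-minor."""
    return [f"{ch}_{st}" for ch in CHANNELS for st in STATISTICS]


def channel_matrix(series: WrenchSeries, geometry: SubjectGeometry) -> np.ndarray:
    """The nine classifier channels as an (n, 9) array, CHANNELS order."""
    moments = joint_moments(series, geometry)
    return np.column_stack(
        [
            series.force,
            series.moment,
            moments.ankle_moment,
            moments.knee_moment,
            sagittal_force_magnitude(series),
        ]
    )


def extract_window(
    time: np.ndarray,
    channels: np.ndarray,
    toe_off_time: float,
    window_ms: float,
    rate: float = RESAMPLE_RATE_HZ,
) -> np.ndarray | None:
    """Fixed-length multichannel window ending at (and including) toe-off.

    On a uniform grid at ``rate`` the window holds exactly
    ``round(window_ms * rate / 1000) + 1`` samples, so every stride yields
    the same length.  Returns ``None`` (with a warning) when the window
    would extend before the start of the series.
    """
    k = int(round(window_ms * rate / 1000.0))
    idx_to = int(np.searchsorted(time, toe_off_time + 1e-9, side="right")) - 1
    if idx_to < 0 or idx_to - k < 0:
        warnings.warn(
            f"window of {window_ms:g} ms before toe-off at {toe_off_time:g} s "
            "extends before the series start; stride dropped"
        )
        return None
    return channels[idx_to - k : idx_to + 1]


def extract_features(window: np.ndarray) -> np.ndarray:
    """The 54-vector of per-channel statistics for one window.

    SD uses the sample (n-1) formula and is defined as 0 for a
    single-sample window.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[1] != len(CHANNELS) or len(w) == 0:
        raise ValueError(f"window must be a non-empty (m, {len(CHANNELS)}) array")
    sd = w.std(axis=0, ddof=1) if len(w) > 1 else np.zeros(w.shape[1])
    stats = np.stack(
        [w.mean(axis=0), sd, w.min(axis=0), w.max(axis=0), w[0], w[-1]]
    )  # (6, 9)
    return stats.T.reshape(-1)  # channel-major to match feature_names()


@dataclass(frozen=True)
class SubjectStreams:
    """One subject's shank-frame stream with segmented strides."""

    subject: int
    series: WrenchSeries
    segments: list
    geometry: SubjectGeometry


@dataclass(frozen=True)
class FeatureTable:
    """Per-stride features with mode labels and grouping keys."""

    X: pd.DataFrame
    y: pd.Series
    subject: pd.Series
    stiffness: pd.Series

    def __len__(self) -> int:
        return len(self.X)

    def groups(self):
        """Iterate (key, row-indexer) over (subject, stiffness) groups."""
        keys = pd.MultiIndex.from_arrays([self.subject, self.stiffness])
        for key in keys.unique():
            yield key, np.flatnonzero(keys == key)


def build_feature_table(
    streams: list[SubjectStreams],
    window_ms: float = DEFAULT_WINDOW_MS,
    rate: float = RESAMPLE_RATE_HZ,
) -> FeatureTable:
    """Resample, window and featurize every included stride.

    Transition-excluded strides are skipped, as are strides whose window
    does not fit in the series.
    """
    rows, labels, subjects, stiffs = [], [], [], []
    for s in streams:
        uniform = resample_uniform(s.series, rate)
        chans = channel_matrix(uniform, s.geometry)
        for seg in s.segments:
            if seg.transition_excluded:
                continue
            win = extract_window(uniform.time, chans, seg.toe_off, window_ms, rate)
            if win is None:
                continue
            rows.append(extract_features(win))
            labels.append(seg.mode)
            subjects.append(s.subject)
            stiffs.append(seg.stiffness_code)
    X = pd.DataFrame(np.asarray(rows), columns=feature_names())
    return FeatureTable(
        X=X,
        y=pd.Series(labels, name="mode"),
        subject=pd.Series(subjects, name="subject"),
        stiffness=pd.Series(stiffs, name="stiffness_code"),
    )


class ShrunkLda(BaseEstimator, ClassifierMixin):
    """Pooled-covariance LDA with diagonal shrinkage.

    The within-class covariance is blended with its own diagonal,
    ``(1 - shrinkage) * S + shrinkage * diag(S)``, which keeps the
    discriminant solvable at the small per-group sample counts this
    pipeline sees.  With ``shrinkage=0`` this is classical LDA (verified
    against scikit-learn's implementation in the test suite); if the
    pooled covariance is singular at 0, a diagonal blend is applied
    automatically.
    """

    def __init__(self, shrinkage: float = 0.0):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        k = len(self.classes_)
        if k < 2:
            raise ValueError("LDA needs at least 2 classes")
        self.means_ = np.stack([X[y_idx == i].mean(axis=0) for i in range(k)])
        self.priors_ = np.bincount(y_idx, minlength=k) / n
        centered = X - self.means_[y_idx]
        dof = max(n - k, 1)
        cov = centered.T @ centered / dof
        self.covariance_ = self._shrink(cov, self.shrinkage)
        try:
            inv_means = np.linalg.solve(self.covariance_, self.means_.T).T
        except np.linalg.LinAlgError:
            # singular pooled covariance: fall back to a diagonal blend
            self.covariance_ = self._shrink(cov, max(self.shrinkage, 0.1))
            inv_means = np.linalg.solve(self.covariance_, self.means_.T).T
        self.coef_ = inv_means
        self.intercept_ = -0.5 * np.einsum("ij,ij->i", self.means_, inv_means) + np.log(
            self.priors_
        )
        return self

    @staticmethod
    def _shrink(cov: np.ndarray, lam: float) -> np.ndarray:
        diag = np.diag(np.diag(cov))
        out = (1.0 - lam) * cov + lam * diag
        # numerical floor against exactly-zero variance directions
        eps = 1e-12 * max(np.trace(cov) / len(cov), 1.0)
        return out + eps * np.eye(len(cov))

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_.T + self.intercept_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def _group_folds(y: np.ndarray, folds: int, seed: int):
    """Stratified fold splits for one group, reducing folds for tiny classes."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(folds, counts.min()))
    if n_splits < int(folds):
        warnings.warn(
            f"smallest class has {counts.min()} members; folds reduced to {n_splits}"
        )
    if n_splits < 2:
        raise ValueError("every class needs at least 2 members for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _cv_predictions(
    table: FeatureTable,
    features: list[str],
    folds: int,
    seed: int,
    shrinkage: float,
):
    """Cross-validated predictions per (subject, stiffness) group.

    Returns (y_true, y_pred) aggregated over all groups and folds.
    """
    Xall = table.X[features].to_numpy()
    yall = table.y.to_numpy()
    trues, preds = [], []
    for _, idx in table.groups():
        Xg, yg = Xall[idx], yall[idx]
        for train, test in _group_folds(yg, folds, seed):
            model = ShrunkLda(shrinkage=shrinkage).fit(Xg[train], yg[train])
            trues.append(yg[test])
            preds.append(model.predict(Xg[test]))
    return np.concatenate(trues), np.concatenate(preds)


def _cv_error(table, features, folds, seed, shrinkage) -> float:
    y_true, y_pred = _cv_predictions(table, features, folds, seed, shrinkage)
    return float(np.mean(y_true != y_pred))


def forward_select(
    table: FeatureTable,
    folds: int = 10,
    seed: int = 0,
    shrinkage: float = 0.01,
    max_features: int | None = None,
) -> list[str]:
    """Greedy forward feature selection under cross-validated error.

    At each step the candidate whose inclusion minimizes the mean CV
    misclassification error is added (ties broken by lowest column index);
    selection stops when no candidate strictly reduces the error.
    """
    if table.y.nunique() < 2:
        raise ValueError("forward selection needs at least 2 classes")
    all_features = list(table.X.columns)
    max_features = max_features or len(all_features)

    # baseline: per-group majority-class prediction
    best_err = 0.0
    total = 0
    for _, idx in table.groups():
        yg = table.y.iloc[idx]
        best_err += len(yg) - yg.value_counts().iloc[0]
        total += len(yg)
    best_err /= total

    selected: list[str] = []
    remaining = list(all_features)
    while remaining and len(selected) < max_features:
        errs = [
            _cv_error(table, selected + [f], folds, seed, shrinkage) for f in remaining
        ]
        j = int(np.argmin(errs))  # argmin keeps the first (lowest-index) tie
        if errs[j] >= best_err:
            break
        best_err = errs[j]
        selected.append(remaining.pop(j))
    return selected


def optimize_window(
    build_table,
    selected: list[str],
    candidates=WINDOW_CANDIDATES_MS,
    folds: int = 10,
    seed: int = 0,
    shrinkage: float = 0.01,
):
    """Refit the reduced-feature model at each candidate window length.

    ``build_table`` maps a window length (ms) to a :class:`FeatureTable`.
    Returns ``(best_window_ms, {window_ms: cv_error})``; ties go to the
    smallest window.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    errors = {}
    for w in candidates:
        table = build_table(w)
        feats = selected if selected else list(table.X.columns)
        errors[w] = _cv_error(table, feats, folds, seed, shrinkage)
    best = min(sorted(errors), key=lambda w: errors[w])  # sorted => smallest wins ties
    return best, errors


@dataclass
class ClassifierReport:
    """Aggregated cross-validation report for the mode classifier."""

    confusion: pd.DataFrame          # true x predicted stride counts
    per_class_accuracy: dict         # mode -> percent
    overall_accuracy: float          # percent, trace / total
    selected_features: list
    window_ms: float
    shrinkage: float
    folds: int
    seed: int
    n_strides: int

    def to_dict(self) -> dict:
        return {
            "confusion_labels": list(self.confusion.index),
            "confusion": self.confusion.to_numpy().tolist(),
            "per_class_accuracy_pct": self.per_class_accuracy,
            "overall_accuracy_pct": self.overall_accuracy,
            "selected_features": list(self.selected_features),
            "window_ms": self.window_ms,
            "shrinkage": self.shrinkage,
            "folds": self.folds,
            "seed": self.seed,
            "n_strides": self.n_strides,
        }


def train_eval_lda(
    table: FeatureTable,
    folds: int = 10,
    seed: int = 0,
    features: list[str] | None = None,
    window_ms: float = DEFAULT_WINDOW_MS,
    shrinkage_grid=SHRINKAGE_GRID,
) -> ClassifierReport:
    """Stratified k-fold evaluation of per-(subject, stiffness) LDA models.

    The shrinkage level is chosen from ``shrinkage_grid`` by the same
    cross-validation (smallest value wins ties), and the confusion matrix
    is aggregated over every group and fold.
    """
    feats = features if features else list(table.X.columns)
    results = {}
    for lam in shrinkage_grid:
        results[lam] = _cv_predictions(table, feats, folds, seed, lam)
    best_lam = min(
        sorted(results), key=lambda lam: np.mean(results[lam][0] != results[lam][1])
    )
    y_true, y_pred = results[best_lam]

    labels = sorted(table.y.unique())
    confusion = pd.crosstab(
        pd.Categorical(y_true, categories=labels),
        pd.Categorical(y_pred, categories=labels),
        dropna=False,
    )
    confusion.index = labels
    confusion.columns = labels
    diag = np.diag(confusion.to_numpy())
    row_sums = confusion.to_numpy().sum(axis=1)
    per_class = {
        lab: float(100.0 * d / r) if r else float("nan")
        for lab, d, r in zip(labels, diag, row_sums)
    }
    return ClassifierReport(
        confusion=confusion,
        per_class_accuracy=per_class,
        overall_accuracy=float(100.0 * diag.sum() / len(y_true)),
        selected_features=feats,
        window_ms=window_ms,
        shrinkage=best_lam,
        folds=folds,
        seed=seed,
        n_strides=len(y_true),
    )


class LocomotionModeClassifier(BaseEstimator):
    """End-to-end mode-classification pipeline as a fit-shaped estimator.

    ``fit`` runs feature extraction, optional forward selection, optional
    window optimization, and the cross-validated per-(subject, stiffness)
    LDA evaluation; the report lands in ``report_``.  ``predict`` applies
    the final models (refit on all data) to new streams.
    """

    def __init__(
        self,
        folds: int = 10,
        seed: int = 0,
        selection_window_ms: float = DEFAULT_WINDOW_MS,
        select_features: bool = True,
        optimize_window_size: bool = True,
        window_candidates=WINDOW_CANDIDATES_MS,
        shrinkage_grid=SHRINKAGE_GRID,
    ):
        self.folds = folds
        self.seed = seed
        self.selection_window_ms = selection_window_ms
        self.select_features = select_features
        self.optimize_window_size = optimize_window_size
        self.window_candidates = window_candidates
        self.shrinkage_grid = shrinkage_grid

    def fit(self, streams: list[SubjectStreams], y=None):
        build = lambda w: build_feature_table(streams, w)  # noqa: E731
        if self.select_features:
            sel_table = build(self.selection_window_ms)
            self.selected_features_ = forward_select(
                sel_table, folds=self.folds, seed=self.seed
            )
        else:
            self.selected_features_ = feature_names()
        if self.optimize_window_size:
            self.window_ms_, self.window_errors_ = optimize_window(
                build,
                self.selected_features_,
                candidates=self.window_candidates,
                folds=self.folds,
                seed=self.seed,
            )
        else:
            self.window_ms_ = self.selection_window_ms
        table = build(self.window_ms_)
        self.report_ = train_eval_lda(
            table,
            folds=self.folds,
            seed=self.seed,
            features=self.selected_features_,
            window_ms=self.window_ms_,
            shrinkage_grid=self.shrinkage_grid,
        )
        # final per-group models refit on all data at the chosen shrinkage
        self.models_ = {}
        for key, idx in table.groups():
            self.models_[key] = ShrunkLda(shrinkage=self.report_.shrinkage).fit(
                table.X[self.selected_features_].to_numpy()[idx],
                table.y.to_numpy()[idx],
            )
        return self

    def predict(self, streams: list[SubjectStreams]) -> pd.DataFrame:
        check_is_fitted(self, "models_")
        table = build_feature_table(streams, self.window_ms_)
        out = []
        for key, idx in table.groups():
            if key not in self.models_:
                raise KeyError(f"no model fitted for (subject, stiffness) group {key}")
            pred = self.models_[key].predict(
                table.X[self.selected_features_].to_numpy()[idx]
            )
            for i, p in zip(idx, pred):
                out.append(
                    {
                        "subject": table.subject.iloc[i],
                        "stiffness_code": table.stiffness.iloc[i],
                        "true_mode": table.y.iloc[i],
                        "predicted_mode": p,
                    }
                )
        return pd.DataFrame(out)
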