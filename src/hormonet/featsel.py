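"""Feature-selection harnesses: tree importance, penalized linear SVC,
gradient-boosted trees.

Each harness fits a model, scores every feature, and keeps the features
scoring above the mean score (the select-from-model convention).  The
reduced set feeds back into training so the before/after effect of
selection can be re-examined on any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

__all__ = ["SelectionResult", "rf_select", "lsvc_select", "gbt_select", "selection_report"]


@dataclass(frozen=True)
class SelectionResult:
    method: str
    selected: np.ndarray  # sorted feature indices
    scores: np.ndarray  # per-feature importance / |coefficient|
    threshold: float
    notes: str = ""

    def __post_init__(self) -> None:
        if len(np.unique(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")
        if len(self.selected) and (
            self.selected.min() < 0 or self.selected.max() >= len(self.scores)
        ):
            raise ValueError("selected index out of range")

    def reduce(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features)[:, self.selected]


def _threshold_select(method: str, scores: np.ndarray, notes: str = "") -> SelectionResult:
    threshold = float(scores.mean())
    selected = np.sort(np.flatnonzero(scores > threshold))
    return SelectionResult(method, selected, scores, threshold, notes)


def rf_select(
    features: np.ndarray,
    labels: np.ndarray,
    n_estimators: int = 300,
    max_depth: int = 9,
    seed: int = 0,
) -> SelectionResult:
    """Random-forest impurity importances, mean-importance threshold."""
    clf = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    clf.fit(features, labels)
    return _threshold_select("rf", clf.feature_importances_)


def lsvc_select(
    features: np.ndarray, labels: np.ndarray, penalty: str = "l2",
    max_iter: int = 300, seed: int = 0,
) -> SelectionResult:
    """|coefficient| of an l2-penalized linear SVC, mean threshold.

    Multiclass problems are handled one-vs-rest with the maximum
    |coefficient| per feature across classes.  ``max_iter`` defaults to
    300, reading the tuning note "estimator value 300" as the iteration
    cap since a linear SVC has no estimator count; flagged in notes.
    """
    clf = LinearSVC(penalty=penalty, max_iter=max_iter, dual="auto", random_state=seed)
    clf.fit(features, labels)
    coef = np.atleast_2d(clf.coef_)
    scores = np.abs(coef).max(axis=0)
    return _threshold_select(
        "lsvc", scores, notes="max_iter=300 interpreted from 'estimator value 300'"
    )


def gbt_select(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> SelectionResult:
    """XGBoost gain importances at library defaults, mean threshold."""
    clf = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    clf.fit(features, labels)
    scores = clf.feature_importances_.astype(float)
    return _threshold_select("gbt", scores)


def selection_report(
    features: np.ndarray,
    labels: np.ndarray,
    result: SelectionResult,
    model_builder,
    split_spec=None,
) -> dict:
    """Before/after-reduction metrics for one selection result.

    Fits ``model_builder()`` on an identical split with the full and the
    reduced feature set, so the effect of selection on model quality can
    be re-examined on any dataset.
    """
    from .datasets import SplitSpec, split as _split
    from .evalx import MetricReport
    import pandas as pd

    split_spec = split_spec or SplitSpec()
    frame = pd.DataFrame(np.asarray(features, dtype=float))
    frame["__label__"] = labels
    train_df, test_df = _split(frame, split_spec, label_col="__label__")

    def fit_eval(cols) -> MetricReport:
        model = model_builder()
        model.fit(train_df[cols].to_numpy(), train_df["__label__"].to_numpy())
        pred = model.predict(test_df[cols].to_numpy())
        return MetricReport.from_predictions(test_df["__label__"].to_numpy(), pred)

    all_cols = [c for c in frame.columns if c != "__label__"]
    reduced_cols = [all_cols[i] for i in result.selected]
    return {
        "method": result.method,
        "n_before": len(all_cols),
        "n_after": len(reduced_cols),
        "before": fit_eval(all_cols),
        "after": fit_eval(reduced_cols),
        "notes": result.notes,
    }
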