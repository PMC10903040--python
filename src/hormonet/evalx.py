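"""Evaluation: confusion counts, the four headline metrics, one-vs-rest
ROC, threefold cross-validation, and before/after-balancing reports.

Per class c the one-vs-rest counts are TP (class-c samples predicted c),
FN (class-c samples predicted otherwise), FP (non-c predicted c) and TN
(non-c predicted non-c); from them

    accuracy  = (TP + TN) / n
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Undefined ratios (empty denominator) are reported as ``None``, never
NaN.  Multiclass summaries are macro-averaged by default, with micro
and weighted variants alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any, Callable, Protocol

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .datasets import SplitSpec
from .smote import SMOTEConfig, balance

__all__ = [
    "confusion_counts", "metrics", "roc", "MetricReport",
    "cross_validate", "smote_ab_report",
]


class Classifier(Protocol):
    def fit(self, x: np.ndarray, y: np.ndarray) -> Any: ...
    def predict(self, x: np.ndarray) -> np.ndarray: ...


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, cls) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for class ``cls``; sums to n."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = y_true == cls
    pos_p = y_pred == cls
    tp = int(np.sum(pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    return tp, tn, fp, fn


def metrics(counts: tuple[int, int, int, int]) -> dict[str, float | None]:
    """Accuracy/precision/recall/F1 from (TP, TN, FP, FN)."""
    tp, tn, fp, fn = counts
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n if n else None
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def roc(scores: np.ndarray, y_true: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Binary ROC curve (FPR, TPR) and trapezoidal area.

    ``y_true`` holds 0/1 membership of the positive class; ``scores``
    are its predicted scores.  The curve runs monotonically from (0, 0)
    to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    fpr, tpr, _ = _sk_roc_curve(np.asarray(y_true).astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class MetricReport:
    """Per-class counts and metrics with macro/micro/weighted summaries."""

    classes: list
    per_class: dict[str, dict[str, float | None]]
    accuracy: float
    macro: dict[str, float | None]
    micro: dict[str, float | None]
    weighted: dict[str, float | None]
    roc_auc: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        return cls(**json.loads(text))

    @classmethod
    def from_predictions(
        cls,
        y_true: np.ndarray,
        y_pred: np.ndarray,
        scores: np.ndarray | None = None,
    ) -> "MetricReport":
        """Build a full report; ``scores`` (n,) binary or (n, k) one-vs-rest
        probabilities enable per-class ROC areas."""
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
        per_class: dict[str, dict] = {}
        support: dict[str, int] = {}
        for c in classes:
            counts = confusion_counts(y_true, y_pred, c)
            m = metrics(counts)
            tp, tn, fp, fn = counts
            per_class[str(c)] = {"tp": tp, "tn": tn, "fp": fp, "fn": fn, **m}
            support[str(c)] = tp + fn
        accuracy = float(np.mean(y_true == y_pred))

        def agg(kind: str) -> dict[str, float | None]:
            vals = {}
            for name in ("precision", "recall", "f1"):
                per = [(per_class[str(c)][name], support[str(c)]) for c in classes]
                defined = [(v, s) for v, s in per if v is not None]
                if not defined:
                    vals[name] = None
                elif kind == "macro":
                    vals[name] = float(np.mean([v for v, _ in defined]))
                else:  # weighted by class support
                    tot = sum(s for _, s in defined)
                    vals[name] = float(sum(v * s for v, s in defined) / tot) if tot else None
            return vals

        # micro: pool counts over classes
        tp = sum(per_class[str(c)]["tp"] for c in classes)
        fp = sum(per_class[str(c)]["fp"] for c in classes)
        fn = sum(per_class[str(c)]["fn"] for c in classes)
        micro_p = tp / (tp + fp) if tp + fp else None
        micro_r = tp / (tp + fn) if tp + fn else None
        micro_f = (
            2 * micro_p * micro_r / (micro_p + micro_r)
            if micro_p and micro_r and micro_p + micro_r
            else None
        )
        roc_auc: dict[str, float] = {}
        if scores is not None:
            scores = np.asarray(scores, dtype=float)
            if scores.ndim == 1 and len(classes) == 2:
                roc_auc[str(classes[1])] = roc(scores, y_true == classes[1])[2]
            elif scores.ndim == 2:
                for j, c in enumerate(classes[: scores.shape[1]]):
                    roc_auc[str(c)] = roc(scores[:, j], y_true == c)[2]
        return cls(
            classes=classes,
            per_class=per_class,
            accuracy=accuracy,
            macro=agg("macro"),
            micro={"precision": micro_p, "recall": micro_r, "f1": micro_f},
            weighted=agg("weighted"),
            roc_auc=roc_auc,
            n=len(y_true),
        )


def cross_validate(
    model_builder: Callable[[], Classifier],
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 3,
    seed: int = 0,
) -> tuple[list[MetricReport], dict[str, dict[str, float]]]:
    """k-fold CV: each sample tested exactly once; returns fold reports
    plus mean/SD of accuracy and the macro metrics."""
    from sklearn.model_selection import KFold

    features = np.asarray(features)
    labels = np.asarray(labels)
    reports: list[MetricReport] = []
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(features):
        model = model_builder()
        model.fit(features[train_idx], labels[train_idx])
        pred = model.predict(features[test_idx])
        reports.append(MetricReport.from_predictions(labels[test_idx], pred))
    summary: dict[str, dict[str, float]] = {}
    for name in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
        if name == "accuracy":
            vals = [r.accuracy for r in reports]
        else:
            vals = [r.macro[name.split("_")[1]] for r in reports]
        vals = [v for v in vals if v is not None]
        summary[name] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
    return reports, summary


def smote_ab_report(
    features: np.ndarray,
    labels: np.ndarray,
    model_builder: Callable[[], Classifier],
    split_spec: SplitSpec = SplitSpec(),
    smote_config: SMOTEConfig = SMOTEConfig(),
) -> dict[str, Any]:
    """Paired before/after-balancing evaluation on one identical split.

    "before" trains on the raw training partition; "after" repeats with
    the training partition balanced (scope ``train_only``) or with the
    whole table balanced before splitting (scope ``full_dataset``).
    Returns both test-set reports and their macro-metric deltas.
    """
    import pandas as pd
    from .datasets import split as _split

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    frame = pd.DataFrame(features)
    frame["__label__"] = labels

    def eval_on(train_f, train_l, test_f, test_l) -> MetricReport:
        model = model_builder()
        model.fit(train_f, train_l)
        return MetricReport.from_predictions(test_l, model.predict(test_f))

    train_df, test_df = _split(frame, split_spec, label_col="__label__")
    tr_f = train_df.drop(columns="__label__").to_numpy()
    tr_l = train_df["__label__"].to_numpy()
    te_f = test_df.drop(columns="__label__").to_numpy()
    te_l = test_df["__label__"].to_numpy()

    before = eval_on(tr_f, tr_l, te_f, te_l)
    if smote_config.scope == "train_only":
        bal_f, bal_l, _ = balance(tr_f, tr_l, smote_config)
        after = eval_on(bal_f, bal_l, te_f, te_l)
    else:  # full_dataset: balance everything, re-split with the same spec
        bal_f, bal_l, _ = balance(features, labels, smote_config)
        bal_frame = pd.DataFrame(bal_f)
        bal_frame["__label__"] = bal_l
        btrain, btest = _split(bal_frame, split_spec, label_col="__label__")
        after = eval_on(
            btrain.drop(columns="__label__").to_numpy(),
            btrain["__label__"].to_numpy(),
            btest.drop(columns="__label__").to_numpy(),
            btest["__label__"].to_numpy(),
        )
    deltas = {
        name: (None if before.macro[name] is None or after.macro[name] is None
               else after.macro[name] - before.macro[name])
        for name in ("precision", "recall", "f1")
    }
    deltas["accuracy"] = after.accuracy - before.accuracy
    return {"before": before, "after": after, "delta": deltas}
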