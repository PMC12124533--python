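"""Stratified cross-validation, confusion matrices, and class metrics.

Evaluation follows the standard protocol for a three-class risk task:
stratified 5-fold cross-validation (each fold holding out ~20% of samples
with class proportions preserved), fold confusion counts pooled into one
3x3 matrix, per-class precision / recall / F1 / support with macro
averages, and a two-class view obtained by merging LowRisk and HighRisk
into a single PCa+ class (the merge is applied to the three-class
predictions; no second model is trained).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .gcms_io import RISK_LEVELS

__all__ = [
    "FoldPlan",
    "EvalReport",
    "make_folds",
    "confusion_and_report",
    "merge_two_class",
    "pool_reports",
]

PCA_POSITIVE = "PCa+"


@dataclass
class FoldPlan:
    """Train/test index sets for stratified k-fold cross-validation."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    n_folds: int
    seed: int

    def __iter__(self):
        return iter(self.folds)


@dataclass
class EvalReport:
    """Confusion matrix plus per-class and macro metrics."""

    classes: tuple[str, ...]
    confusion: np.ndarray                 # rows = true, cols = predicted
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    zero_division_flags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "zero_division_flags": self.zero_division_flags,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(
            classes=tuple(d["classes"]),
            confusion=np.asarray(d["confusion"], dtype=int),
            precision=d["precision"],
            recall=d["recall"],
            f1=d["f1"],
            support={k: int(v) for k, v in d["support"].items()},
            accuracy=d["accuracy"],
            macro_precision=d["macro_precision"],
            macro_recall=d["macro_recall"],
            macro_f1=d["macro_f1"],
            zero_division_flags=list(d["zero_division_flags"]),
        )

    def rounded(self, decimals: int = 2) -> dict:
        """Metrics at the conventional two-decimal reporting precision."""
        return {
            "precision": {k: round(v, decimals) for k, v in self.precision.items()},
            "recall": {k: round(v, decimals) for k, v in self.recall.items()},
            "f1": {k: round(v, decimals) for k, v in self.f1.items()},
            "accuracy": round(self.accuracy, decimals),
            "macro_f1": round(self.macro_f1, decimals),
        }


def make_folds(risks: np.ndarray, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Deterministic stratified k-fold plan over the risk labels.

    Test sets partition the dataset and each preserves class proportions to
    within one sample; with 365 samples and 5 folds every test set has 73.
    """
    from sklearn.model_selection import StratifiedKFold

    risks = np.asarray(risks)
    _, counts = np.unique(risks, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; need >= {n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [
        (train.copy(), test.copy())
        for train, test in skf.split(np.zeros(len(risks)), risks)
    ]
    return FoldPlan(folds=folds, n_folds=n_folds, seed=seed)


def _report_from_confusion(classes, cm: np.ndarray) -> EvalReport:
    precision, recall, f1, support = {}, {}, {}, {}
    flags = []
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        if tp + fp == 0:
            precision[cls] = 0.0
            flags.append(f"precision[{cls}]: no predictions")
        else:
            precision[cls] = float(tp / (tp + fp))
        if tp + fn == 0:
            recall[cls] = 0.0
            flags.append(f"recall[{cls}]: no true samples")
        else:
            recall[cls] = float(tp / (tp + fn))
        pr, rc = precision[cls], recall[cls]
        f1[cls] = float(2 * pr * rc / (pr + rc)) if pr + rc > 0 else 0.0
        support[cls] = int(cm[i, :].sum())
    total = cm.sum()
    return EvalReport(
        classes=tuple(classes),
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        accuracy=float(np.trace(cm) / total) if total else 0.0,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
        zero_division_flags=flags,
    )


def confusion_and_report(
    y_true, y_pred, classes: tuple[str, ...] = RISK_LEVELS
) -> EvalReport:
    """Confusion matrix (rows = true, cols = predicted) and class metrics.

    Precision = TP / (TP + FP), recall = TP / (TP + FN),
    F1 = 2PR / (P + R); macro averages are unweighted class means.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    unknown = set(y_true) | set(y_pred)
    unknown -= set(classes)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} outside declared classes {classes}")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return _report_from_confusion(classes, cm)


def merge_two_class(y_true, y_pred) -> EvalReport:
    """Metrics after merging LowRisk + HighRisk into PCa+ (Control kept).

    Cross-risk confusions (LowRisk predicted as HighRisk and vice versa)
    vanish under the merge, so two-class accuracy is never below the
    three-class accuracy of the same predictions.
    """
    mapping = {"Control": "Control", "LowRisk": PCA_POSITIVE, "HighRisk": PCA_POSITIVE}
    yt = np.array([mapping[v] for v in np.asarray(y_true)])
    yp = np.array([mapping[v] for v in np.asarray(y_pred)])
    return confusion_and_report(yt, yp, classes=("Control", PCA_POSITIVE))


def pool_reports(fold_results: list[tuple[np.ndarray, np.ndarray]],
                 classes: tuple[str, ...] = RISK_LEVELS) -> tuple[EvalReport, dict]:
    """Pool per-fold (y_true, y_pred) pairs into one report.

    Confusion counts are summed across folds before metrics are computed;
    per-fold accuracies are returned alongside as mean +/- SD.
    """
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc = []
    for yt, yp in fold_results:
        sub = np.zeros_like(cm)
        for t, p in zip(yt, yp):
            sub[index[t], index[p]] += 1
        cm += sub
        fold_acc.append(float(np.trace(sub) / sub.sum()) if sub.sum() else 0.0)
    report = _report_from_confusion(classes, cm)
    per_fold = {
        "fold_accuracy": fold_acc,
        "mean_accuracy": float(np.mean(fold_acc)),
        "sd_accuracy": float(np.std(fold_acc)),
    }
    return report, per_fold
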