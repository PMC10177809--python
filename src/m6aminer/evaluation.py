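"""Binary-classifier evaluation: six metrics, stratified k-fold
cross-validation, the independent test, and ROC/PR curves.

Metric definitions follow the standard confusion-table forms:
Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC = (TP+TN)/total,
F1 = 2TP/(2TP+FP+FN), and MCC = (TP*TN - FP*FN) / sqrt of the product of
the four marginal totals. AUC is the area under the ROC curve computed from
the score ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVReport",
    "compute_metrics",
    "cross_validate",
    "independent_test",
    "curves",
]

METRIC_NAMES = ("ACC", "AUC", "Sn", "Sp", "F1", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-table counts at a fixed decision threshold."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class MetricSet:
    """The six evaluation metrics for one fitted model on one dataset."""

    acc: float
    auc: float
    sn: float
    sp: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.acc,
            "AUC": self.auc,
            "Sn": self.sn,
            "Sp": self.sp,
            "F1": self.f1,
            "MCC": self.mcc,
        }

    def as_array(self) -> np.ndarray:
        return np.array([self.acc, self.auc, self.sn, self.sp, self.f1, self.mcc])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "MetricSet":
        return cls(*(float(v) for v in arr))


def metrics_from_counts(counts: ConfusionCounts, auc: float) -> MetricSet:
    """Assemble a MetricSet from confusion counts plus a precomputed AUC.

    MCC with a zero marginal is defined as 0 (the no-information value)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    if total == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return MetricSet(acc=acc, auc=auc, sn=sn, sp=sp, f1=f1, mcc=mcc)


def compute_metrics(
    y_true: Sequence[int], y_score: Sequence[float], threshold: float = 0.5
) -> MetricSet:
    """Compute the six metrics from true labels and class-1 scores.

    Hard labels are ``score >= threshold``. Raises if only one class is
    present, since AUC and MCC are undefined there.
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape:
        raise ValueError("y_true and y_score must have the same length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present: AUC and MCC are undefined otherwise")
    auc = float(roc_auc_score(y_true, y_score))
    counts = ConfusionCounts.from_predictions(y_true, (y_score >= threshold).astype(int))
    return metrics_from_counts(counts, auc)


@dataclass
class CVReport:
    """Per-fold metrics plus their mean and (sample) standard deviation."""

    fold_metrics: list[MetricSet]
    mean: MetricSet = field(init=False)
    sd: MetricSet = field(init=False)

    def __post_init__(self) -> None:
        arr = np.vstack([m.as_array() for m in self.fold_metrics])
        self.mean = MetricSet.from_array(arr.mean(axis=0))
        ddof = 1 if len(self.fold_metrics) > 1 else 0
        self.sd = MetricSet.from_array(arr.std(axis=0, ddof=ddof))

    def as_frame(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.fold_metrics]
        df = pd.DataFrame(rows, index=[f"fold{i + 1}" for i in range(len(rows))])
        df.loc["mean"] = self.mean.as_dict()
        df.loc["sd"] = self.sd.as_dict()
        return df


ModelFactory = Callable[[pd.DataFrame, np.ndarray], Callable[[pd.DataFrame], np.ndarray]]
"""A model factory fits on (X_train, y_train) and returns a scorer mapping
X_validation to class-1 probabilities."""


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[int],
    model_factory: ModelFactory,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold cross-validation.

    Each fold serves exactly once as the validation set; the report carries
    per-fold metrics and their mean +- SD. Folds are stratified to preserve
    the class ratio and are deterministic under ``seed``.
    """
    y = np.asarray(y).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[MetricSet] = []
    for train_idx, val_idx in skf.split(X, y):
        y_tr, y_va = y[train_idx], y[val_idx]
        if len(np.unique(y_va)) < 2:
            raise ValueError(
                "a validation fold contains a single class; use stratification or a "
                "different seed"
            )
        scorer = model_factory(X.iloc[train_idx], y_tr)
        scores = np.asarray(scorer(X.iloc[val_idx]), dtype=float)
        fold_metrics.append(compute_metrics(y_va, scores, threshold))
    return CVReport(fold_metrics)


def independent_test(bundle, X_test: pd.DataFrame, y_test: Sequence[int]) -> MetricSet:
    """Evaluate a trained :class:`~m6aminer.modeling.ModelBundle` on held-out
    data whose ids must be disjoint from the training ids (leakage guard)."""
    from m6aminer.modeling import predict

    train_ids = set(bundle.metadata.get("training_ids", ()))
    overlap = train_ids & set(map(str, X_test.index))
    if overlap:
        raise ValueError(
            f"independent test set overlaps training set: {sorted(overlap)[:5]}"
            f"{'...' if len(overlap) > 5 else ''}"
        )
    scores, _ = predict(bundle, X_test)
    return compute_metrics(np.asarray(y_test), scores)


def curves(
    y_true: Sequence[int], y_score: Sequence[float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROC and precision-recall point lists.

    Returns ``(roc, pr)`` DataFrames; the ROC frame has columns fpr/tpr/
    threshold with endpoints (0,0) and (1,1), the PR frame precision/recall
    with precision 1 at recall 0 by convention.
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y_true, y_score)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    precision, recall, _ = precision_recall_curve(y_true, y_score)
    pr = pd.DataFrame({"precision": precision, "recall": recall})
    return roc, pr


def auc_from_roc(roc: pd.DataFrame) -> float:
    """Trapezoidal area under a ROC point list (consistency check for
    :func:`compute_metrics`)."""
    return float(np.trapezoid(roc["tpr"], roc["fpr"]))


def plot_curves(roc: pd.DataFrame, pr: pd.DataFrame, out_path) -> None:
    """Optional ROC + PR plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(roc["fpr"], roc["tpr"])
    ax1.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax1.set_xlabel("1 - specificity")
    ax1.set_ylabel("sensitivity")
    ax1.set_title("ROC")
    ax2.plot(pr["recall"], pr["precision"])
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    ax2.set_title("Precision-recall")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
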