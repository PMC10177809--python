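"""Feature ranking by extremely-randomized-trees importance and subset
choice by the equidistant (fixed-step) prefix search.

The search evaluates nested prefixes of the importance ranking at sizes
step, 2*step, ... up to the full feature count (the final prefix is always
the complete set, even when the total is not a multiple of the step) and
keeps the size with the best mean cross-validated AUC, breaking ties toward
the smaller subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier

from m6aminer.evaluation import MetricSet

__all__ = [
    "ImportanceRanking",
    "SubsetSearchResult",
    "rank_features",
    "rank_features_multi",
    "prefix_sizes",
    "equidistant_search",
]


@dataclass(frozen=True)
class ImportanceRanking:
    """Features in descending importance order with their scores."""

    feature_names: tuple[str, ...]
    scores: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.scores):
            raise ValueError("names/scores length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names in ranking")
        if any(s2 > s1 for s1, s2 in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")
        if any(s < 0 for s in self.scores):
            raise ValueError("importance scores must be non-negative")

    def top(self, n: int) -> list[str]:
        return list(self.feature_names[:n])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.feature_names) + 1),
                "feature_name": self.feature_names,
                "score": self.scores,
            }
        )

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _validate_xy(X: pd.DataFrame, y: np.ndarray) -> None:
    if X.isna().any().any():
        raise ValueError("feature matrix contains NaN")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be represented to rank features")


def _sorted_ranking(names: Sequence[str], scores: np.ndarray, seed: int) -> ImportanceRanking:
    # descending score, ties broken stably by feature name for reproducibility
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return ImportanceRanking(
        feature_names=tuple(names[i] for i in order),
        scores=tuple(float(scores[i]) for i in order),
        seed=seed,
    )


def rank_features(
    X: pd.DataFrame, y: Sequence[int], seed: int = 0, n_estimators: int = 100
) -> ImportanceRanking:
    """Rank all features by impurity-based importance from an
    ``ExtraTreesClassifier`` ensemble. Deterministic given ``seed``."""
    y = np.asarray(y).astype(int)
    _validate_xy(X, y)
    forest = ExtraTreesClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    ).fit(X.values, y)
    return _sorted_ranking(list(X.columns), forest.feature_importances_, seed)


def rank_features_multi(
    datasets: Sequence[tuple[pd.DataFrame, Sequence[int]]],
    seed: int = 0,
    n_estimators: int = 100,
) -> ImportanceRanking:
    """Rank per sub-training dataset and average normalized importance
    scores across datasets (all matrices must share identical columns)."""
    if not datasets:
        raise ValueError("no datasets given")
    columns = list(datasets[0][0].columns)
    acc = np.zeros(len(columns))
    for X, y in datasets:
        if list(X.columns) != columns:
            raise ValueError("all datasets must share identical feature columns")
        r = rank_features(X, y, seed=seed, n_estimators=n_estimators)
        by_name = dict(zip(r.feature_names, r.scores))
        scores = np.array([by_name[c] for c in columns])
        total = scores.sum()
        acc += scores / total if total > 0 else scores
    return _sorted_ranking(columns, acc / len(datasets), seed)


def prefix_sizes(total: int, step: int = 50) -> list[int]:
    """The equidistant evaluation schedule: step, 2*step, ..., plus the full
    feature count when it is not a multiple of the step."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if total < 1:
        raise ValueError("total must be >= 1")
    sizes = list(range(step, total + 1, step))
    if not sizes or sizes[-1] != total:
        sizes.append(total)
    return sizes


@dataclass
class SubsetSearchResult:
    """Outcome of the equidistant prefix search."""

    subset_sizes: list[int]
    metric_per_size: list[tuple[MetricSet, MetricSet]]  # (mean, sd) per size
    best_size: int

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.subset_sizes, self.subset_sizes[1:])):
            raise ValueError("subset sizes must be strictly increasing")
        if self.best_size not in self.subset_sizes:
            raise ValueError("best_size must be one of the evaluated sizes")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for size, (mean, sd) in zip(self.subset_sizes, self.metric_per_size):
            row = {"size": size}
            row.update({f"{k}_mean": v for k, v in mean.as_dict().items()})
            row.update({f"{k}_sd": v for k, v in sd.as_dict().items()})
            rows.append(row)
        return pd.DataFrame(rows)


Evaluator = Callable[[pd.DataFrame, Sequence[int]], tuple[MetricSet, MetricSet]]
"""Evaluates one feature subset, returning (mean, sd) MetricSets — e.g. a
cross-validation over one or several sub-training datasets."""


def equidistant_search(
    ranking: ImportanceRanking,
    X: pd.DataFrame,
    y: Sequence[int],
    evaluator: Evaluator,
    step: int = 50,
) -> SubsetSearchResult:
    """Evaluate nested top-k prefixes of the ranking every ``step`` features
    and select the size maximizing mean AUC (ties -> smaller size)."""
    missing = [f for f in ranking.feature_names if f not in X.columns]
    if missing:
        raise ValueError(f"ranked features missing from X: {missing[:5]}")
    sizes = prefix_sizes(len(ranking.feature_names), step)
    results: list[tuple[MetricSet, MetricSet]] = []
    for size in sizes:
        cols = ranking.top(size)
        try:
            results.append(evaluator(X[cols], y))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed at subset size {size}") from exc
    aucs = [mean.auc for mean, _ in results]
    best_size = sizes[int(np.argmax(aucs))]  # argmax takes the first (smallest) on ties
    return SubsetSearchResult(subset_sizes=sizes, metric_per_size=results, best_size=best_size)
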