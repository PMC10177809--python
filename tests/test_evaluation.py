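import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from m6aminer.evaluation import (
    ConfusionCounts,
    auc_from_roc,
    compute_metrics,
    cross_validate,
    curves,
    independent_test,
    metrics_from_counts,
)
from m6aminer.modeling import ModelConfig, make_model_factory, train


def test_perfect_classifier():
    y = [0, 0, 1, 1]
    s = [0.1, 0.2, 0.8, 0.9]
    m = compute_metrics(y, s)
    assert (m.acc, m.auc, m.sn, m.sp, m.f1, m.mcc) == (1, 1, 1, 1, 1, 1)


def test_random_scores_auc_near_half():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 20000)
    s = rng.random(20000)
    assert compute_metrics(y, s).auc == pytest.approx(0.5, abs=0.02)


def test_hand_computed_confusion_table():
    # TP=3, TN=2, FP=1, FN=1 substituted into the standard formulas
    m = metrics_from_counts(ConfusionCounts(tp=3, tn=2, fp=1, fn=1), auc=0.8)
    assert m.acc == pytest.approx(5 / 7)
    assert m.sn == pytest.approx(3 / 4)
    assert m.sp == pytest.approx(2 / 3)
    assert m.f1 == pytest.approx(6 / 8)
    assert m.mcc == pytest.approx((3 * 2 - 1 * 1) / math.sqrt(4 * 4 * 3 * 3))


def test_single_class_raises():
    with pytest.raises(ValueError, match="both classes"):
        compute_metrics([1, 1, 1], [0.2, 0.4, 0.9])


def test_metric_identities_all_small_tables():
    """ACC = (Sn*P + Sp*N)/(P+N) over every confusion table with P,N <= 6."""
    for tp, fn, tn, fp in product(range(7), repeat=4):
        P, N = tp + fn, tn + fp
        if P == 0 or N == 0:
            continue
        m = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn), auc=0.5)
        assert m.acc == pytest.approx((m.sn * P + m.sp * N) / (P + N))
        assert -1 <= m.mcc <= 1
        assert 0 <= m.f1 <= 1


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 500)
    y[:2] = [0, 1]
    s = rng.random(500)
    a1 = compute_metrics(y, s).auc
    a2 = compute_metrics(y, np.exp(5 * s)).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_curves_endpoints_and_auc_consistency():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 300)
    y[:2] = [0, 1]
    s = rng.random(300) + 0.3 * y
    roc, pr = curves(y, s)
    assert (roc["fpr"].iloc[0], roc["tpr"].iloc[0]) == (0, 0)
    assert (roc["fpr"].iloc[-1], roc["tpr"].iloc[-1]) == (1, 1)
    assert auc_from_roc(roc) == pytest.approx(compute_metrics(y, s).auc, abs=1e-9)
    # PR convention: precision 1 at recall 0
    assert pr["precision"].iloc[-1] == 1.0 and pr["recall"].iloc[-1] == 0.0


def _toy_xy(n=100, seed=0):
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    X = pd.DataFrame(
        {"signal": y + 0.01 * rng.standard_normal(n), "noise": rng.standard_normal(n)},
        index=[f"s{i}" for i in range(n)],
    )
    return X, y


def test_cross_validate_partitions_and_determinism():
    X, y = _toy_xy()
    seen = []
    factory = make_model_factory(ModelConfig(iterations=20, depth=3, seed=0))

    def recording_factory(X_tr, y_tr):
        scorer = factory(X_tr, y_tr)

        def wrapped(X_va):
            seen.extend(X_va.index)
            return scorer(X_va)

        return wrapped

    r1 = cross_validate(X, y, recording_factory, k=10, seed=5)
    assert sorted(seen) == sorted(X.index)  # every sample validated once
    r2 = cross_validate(X, y, factory, k=10, seed=5)
    assert np.array_equal(r1.mean.as_array(), r2.mean.as_array())


def test_cross_validate_stratification_preserves_ratio():
    X, y = _toy_xy(120)
    counts = []

    def factory(X_tr, y_tr):
        counts.append(y_tr.mean())
        return lambda X_va: np.full(len(X_va), 0.5) + 0.001 * np.arange(len(X_va)) * (
            2 * np.asarray([1] * len(X_va)) - 1
        )

    # stratified folds keep the 50:50 ratio in every training fold
    try:
        cross_validate(X, y, factory, k=10, seed=1)
    except ValueError:
        pass  # constant-ish scores may break AUC; ratio check is what matters
    assert all(c == pytest.approx(0.5, abs=0.01) for c in counts)


def test_cv_report_mean_sd():
    X, y = _toy_xy()
    report = cross_validate(
        X, y, make_model_factory(ModelConfig(iterations=20, depth=3)), k=5, seed=0
    )
    arr = np.vstack([m.as_array() for m in report.fold_metrics])
    assert np.allclose(report.mean.as_array(), arr.mean(axis=0))
    assert np.allclose(report.sd.as_array(), arr.std(axis=0, ddof=1))


def test_independent_test_leakage_guard():
    X, y = _toy_xy()
    bundle = train(X, y, ModelConfig(iterations=20, depth=3))
    with pytest.raises(ValueError, match="overlap"):
        independent_test(bundle, X, y)
    # disjoint ids pass
    X2, y2 = _toy_xy(seed=9)
    X2.index = [f"t{i}" for i in range(len(X2))]
    m = independent_test(bundle, X2, y2)
    assert m.auc > 0.9  # same separable generative law
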