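import numpy as np
import pandas as pd
import pytest

from m6aminer.evaluation import cross_validate
from m6aminer.modeling import (
    DEFAULT_GRID,
    GridSpec,
    ModelBundle,
    ModelConfig,
    TUNED_CONFIG,
    grid_search,
    make_model_factory,
    predict,
    train,
)


def _separable_xy(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    X = pd.DataFrame(
        {
            "a": y * 2.0 + rng.normal(0, 0.05, n),
            "b": rng.standard_normal(n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    return X, y


def test_separable_training_accuracy():
    X, y = _separable_xy()
    bundle = train(X, y, ModelConfig(iterations=50, depth=3))
    _, labels = predict(bundle, X)
    assert np.array_equal(labels, y)


def test_refit_same_seed_identical_probabilities():
    X, y = _separable_xy()
    cfg = ModelConfig(iterations=50, depth=4, seed=7)
    s1, _ = predict(train(X, y, cfg), X)
    s2, _ = predict(train(X, y, cfg), X)
    assert np.array_equal(s1, s2)


def test_probabilities_bounded():
    X, y = _separable_xy()
    bundle = train(X, y, ModelConfig(iterations=30, depth=3))
    rng = np.random.default_rng(1)
    X_new = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
    scores, labels = predict(bundle, X_new)
    assert np.all((scores >= 0) & (scores <= 1))
    assert set(labels) <= {0, 1}


def test_single_class_raises():
    X, _ = _separable_xy()
    with pytest.raises(ValueError, match="single class"):
        train(X, np.zeros(len(X), dtype=int))


def test_column_mismatch_and_reorder_rejected():
    X, y = _separable_xy()
    bundle = train(X, y, ModelConfig(iterations=10, depth=3))
    with pytest.raises(ValueError, match="wrong order"):
        predict(bundle, X[["b", "a"]])
    with pytest.raises(ValueError, match="missing"):
        predict(bundle, X[["a"]].assign(c=0.0))


def test_persistence_roundtrip_bitwise(tmp_path):
    X, y = _separable_xy()
    bundle = train(X, y, ModelConfig(iterations=40, depth=4, seed=3))
    s_mem, _ = predict(bundle, X)
    bundle.save(tmp_path / "m")
    loaded = ModelBundle.load(tmp_path / "m")
    s_disk, _ = predict(loaded, X)
    assert np.array_equal(s_mem, s_disk)
    assert loaded.feature_names == bundle.feature_names
    assert loaded.config == bundle.config


def test_null_labels_cv_auc_near_half():
    rng = np.random.default_rng(5)
    n = 600
    X = pd.DataFrame(
        rng.standard_normal((n, 10)),
        columns=[f"f{i}" for i in range(10)],
        index=[f"s{i}" for i in range(n)],
    )
    y = rng.permutation(np.tile([0, 1], n // 2))
    report = cross_validate(
        X, y, make_model_factory(ModelConfig(iterations=30, depth=3, seed=0)), k=5, seed=0
    )
    # 95% interval for a null AUC averaged over 5 folds of 120 samples
    assert report.mean.auc == pytest.approx(0.5, abs=0.06)


def test_default_grid_matches_protocol():
    assert len(DEFAULT_GRID) == 6 * 10 * 6 == 360
    assert sum(1 for _ in DEFAULT_GRID.cells()) == 360


def test_grid_of_one_cell_returns_that_config():
    X, y = _separable_xy(100)
    grid = GridSpec((20,), (3,), (0.1,))
    cfg = grid_search(X, y, grid, cv_folds=3, seed=0)
    assert (cfg.iterations, cfg.depth, cfg.learning_rate) == (20, 3, 0.1)


def test_grid_search_beats_or_ties_any_member():
    X, y = _separable_xy(200, seed=2)
    grid = GridSpec((10, 40), (2, 4), (0.05, 0.2))
    best, results = grid_search(X, y, grid, cv_folds=3, seed=0, return_results=True)
    assert len(results) == 8
    best_row = results[
        (results.iterations == best.iterations)
        & (results.depth == best.depth)
        & (results.learning_rate == best.learning_rate)
    ]
    assert best_row["mean_auc"].iloc[0] == results["mean_auc"].max()


def test_grid_tie_breaks_toward_smaller():
    X, y = _separable_xy(200)  # trivially separable: many cells reach AUC 1.0
    grid = GridSpec((10, 50), (2, 5), (0.1, 0.3))
    best, results = grid_search(X, y, grid, cv_folds=3, seed=0, return_results=True)
    top = results[results.mean_auc == results.mean_auc.max()]
    assert best.iterations == top.iterations.min()


def test_monotone_signal_auc(small_signal_xy):
    """CV AUC is non-decreasing in planted effect size (allowing noise)."""
    from m6aminer.encoders import encode_matrix
    from m6aminer.synthetic import GeneratorSpec, generate

    aucs = []
    for effect in (0.0, 0.5, 1.0):
        ds = generate(GeneratorSpec(n_pos=250, n_neg=250, effect_size=effect, seed=21))
        X = encode_matrix(ds.windows)
        y = np.array([w.label for w in ds.windows])
        rep = cross_validate(
            X, y, make_model_factory(ModelConfig(iterations=60, depth=4, seed=0)), k=4, seed=0
        )
        aucs.append(rep.mean.auc)
    assert aucs[0] < aucs[1] < aucs[2]
    assert aucs[2] - aucs[0] > 0.2


def test_tuned_preset_matches_reference_settings():
    assert (TUNED_CONFIG.iterations, TUNED_CONFIG.depth, TUNED_CONFIG.learning_rate) == (
        2000,
        9,
        0.03,
    )


def test_multiclass_compat_flag_equivalent_ranking():
    X, y = _separable_xy(120)
    s_bin, _ = predict(train(X, y, ModelConfig(iterations=30, depth=3)), X)
    s_mc, _ = predict(
        train(X, y, ModelConfig(iterations=30, depth=3, loss_function="MultiClass")), X
    )
    # same discrimination even if calibration differs
    from sklearn.metrics import roc_auc_score

    assert roc_auc_score(y, s_mc) == pytest.approx(roc_auc_score(y, s_bin), abs=0.01)
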