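"""End-to-end orchestration: simulate/load -> encode -> split -> rank ->
select -> (tune) -> train -> cross-validate -> independent test.

Every run writes a self-describing artifact tree under the output
directory: a MANIFEST.json with the full configuration, seeds and package
version; split manifests; the importance ranking; the subset-search table;
the trained model bundle; and all metric reports as JSON/CSV. Any number in
a report is recomputable from the persisted manifests alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from m6aminer import __version__
from m6aminer.datasets import (
    aggregate_over_splits,
    make_subtraining_splits,
    write_split_manifest,
)
from m6aminer.encoders import EncoderConfig, encode_matrix
from m6aminer.evaluation import cross_validate, independent_test
from m6aminer.modeling import GridSpec, ModelConfig, grid_search, make_model_factory, train
from m6aminer.selection import equidistant_search, rank_features_multi
from m6aminer.sequence_io import (
    LabeledDataset,
    attach_labels,
    read_fasta,
    read_labels,
    write_fasta,
    write_labels,
)
from m6aminer.synthetic import GeneratorSpec, generate


@dataclass
class RunConfig:
    """Everything one pipeline run needs; all seeds are recorded in the
    output manifest."""

    out_dir: str | Path = "m6aminer-run"
    # input: either FASTA+labels paths, or a generator spec for simulation
    fasta_path: str | Path | None = None
    labels_path: str | Path | None = None
    generator: GeneratorSpec | None = None
    test_fraction: float = 0.1  # held out for the independent test
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    n_splits: int = 10
    selection_step: int = 50
    selection_tree_count: int = 100
    cv_folds: int = 10
    grid: GridSpec | None = None  # None skips hyperparameter tuning
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def _load_input(config: RunConfig) -> LabeledDataset:
    if config.fasta_path is not None:
        if config.labels_path is None:
            raise ValueError("labels_path is required alongside fasta_path")
        windows = read_fasta(config.fasta_path, config.encoder.window_length)
        return attach_labels(windows, read_labels(config.labels_path))
    return generate(config.generator or GeneratorSpec(seed=config.seed))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the run directory.

    Reruns with an identical config are byte-identical in their metric
    reports. A stage failure raises with the stage name; artifacts written
    up to that point remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "input"
        dataset = _load_input(config)
        write_fasta(dataset.windows, out / "windows.fa")
        write_labels(dataset, out / "labels.tsv")

        stage = "holdout"
        rng = np.random.default_rng(config.seed)
        pos_ids = [w.id for w in dataset.positives]
        neg_ids = [w.id for w in dataset.negatives]
        n_test_pos = int(round(len(pos_ids) * config.test_fraction))
        n_test_neg = int(round(len(neg_ids) * config.test_fraction))
        test_ids = set(rng.choice(pos_ids, n_test_pos, replace=False)) | set(
            rng.choice(neg_ids, n_test_neg, replace=False)
        )
        train_set = LabeledDataset([w for w in dataset if w.id not in test_ids])
        test_set = LabeledDataset([w for w in dataset if w.id in test_ids])

        stage = "split"
        splits = make_subtraining_splits(train_set, config.n_splits, config.seed)
        write_split_manifest(splits, out / "splits.tsv")

        stage = "encode"
        split_data = []
        for s in splits:
            ds = s.as_dataset()
            X = encode_matrix(ds.windows, config.encoder)
            y = np.array([w.label for w in ds.windows])
            split_data.append((X, y))

        stage = "rank"
        ranking = rank_features_multi(
            split_data, seed=config.seed, n_estimators=config.selection_tree_count
        )
        ranking.save_tsv(out / "ranking.tsv")

        stage = "select"
        X1, y1 = split_data[0]

        def evaluator(X_sub: pd.DataFrame, y_sub):
            report = cross_validate(
                X_sub,
                y_sub,
                make_model_factory(config.model),
                k=config.cv_folds,
                seed=config.seed,
            )
            return report.mean, report.sd

        if config.selection_step >= len(ranking.feature_names):
            best_features = list(ranking.feature_names)
            search = None
        else:
            search = equidistant_search(
                ranking, X1, y1, evaluator, step=config.selection_step
            )
            search.to_frame().to_csv(out / "subset_search.csv", index=False)
            best_features = ranking.top(search.best_size)

        stage = "tune"
        model_cfg = config.model
        if config.grid is not None:
            model_cfg, grid_results = grid_search(
                X1[best_features],
                y1,
                config.grid,
                cv_folds=config.cv_folds,
                seed=config.seed,
                base_config=config.model,
                return_results=True,
            )
            grid_results.to_csv(out / "grid_search.csv", index=False)

        stage = "cv"
        per_split = []
        for X, y in split_data:
            report = cross_validate(
                X[best_features],
                y,
                make_model_factory(model_cfg),
                k=config.cv_folds,
                seed=config.seed,
            )
            per_split.append(report.mean)
        grand_mean, grand_sd = aggregate_over_splits(per_split)
        cv_payload = {
            "per_split_mean": [m.as_dict() for m in per_split],
            "grand_mean": grand_mean.as_dict(),
            "grand_sd": grand_sd.as_dict(),
        }
        (out / "cv_report.json").write_text(json.dumps(cv_payload, indent=2))

        stage = "train"
        bundle = train(
            X1[best_features],
            y1,
            model_cfg,
            encoder_config_hash=config.encoder.config_hash(),
            metadata={"dataset_id": "split1", "run_seed": config.seed},
        )
        bundle.save(out / "model")

        stage = "test"
        if len(test_set) and test_set.positive_count and test_set.negative_count:
            X_test = encode_matrix(test_set.windows, config.encoder)[best_features]
            y_test = np.array([w.label for w in test_set.windows])
            test_metrics = independent_test(bundle, X_test, y_test)
            (out / "independent_test.json").write_text(
                json.dumps(test_metrics.as_dict(), indent=2)
            )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": _jsonable(config),
            "encoder_config_hash": config.encoder.config_hash(),
            "n_windows": len(dataset),
            "n_train": len(train_set),
            "n_test": len(test_set),
            "n_features_total": len(ranking.feature_names),
            "selected_size": len(best_features),
            "model_config": model_cfg.as_dict(),
        }
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
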