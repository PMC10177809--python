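"""Experiment dataset layout: balanced sub-training splits and aggregation.

The benchmark this emulates is heavily imbalanced (about ten negatives per
positive). To train on roughly 1:1 data without discarding negatives, the
negative set is shuffled and partitioned into ``n_splits`` disjoint,
near-equal shards; each shard is paired with the full positive set to form
one sub-training dataset. Metrics are then averaged over the splits, with
the spread across splits reported as a sample standard deviation.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from m6aminer.evaluation import MetricSet
from m6aminer.sequence_io import LabeledDataset, SequenceWindow

__all__ = [
    "SubTrainingSplit",
    "make_subtraining_splits",
    "aggregate_over_splits",
    "write_split_manifest",
    "read_split_manifest",
    "cdhit_reduce",
]


@dataclass
class SubTrainingSplit:
    """One balanced sub-training dataset: all positives + one negative shard."""

    index: int
    positives: list[SequenceWindow]
    negatives: list[SequenceWindow]

    def as_dataset(self) -> LabeledDataset:
        return LabeledDataset(self.positives + self.negatives)

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def make_subtraining_splits(
    dataset: LabeledDataset, n_splits: int = 10, seed: int = 0
) -> list[SubTrainingSplit]:
    """Partition the negatives into ``n_splits`` disjoint near-equal shards
    (sizes differ by at most 1) and pair each with the full positive set.

    Shuffling is deterministic under ``seed``; different seeds change shard
    membership but never shard sizes.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    positives = dataset.positives
    negatives = dataset.negatives
    if len(negatives) < n_splits:
        raise ValueError(
            f"need at least {n_splits} negatives to build {n_splits} shards, "
            f"got {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(negatives))
    shards = np.array_split(order, n_splits)
    return [
        SubTrainingSplit(
            index=i + 1,
            positives=list(positives),
            negatives=[negatives[j] for j in shard],
        )
        for i, shard in enumerate(shards)
    ]


def aggregate_over_splits(results: list[MetricSet]) -> tuple[MetricSet, MetricSet]:
    """Per-metric mean and sample standard deviation over split-level results.

    The SD is taken over the per-split means (not over individual CV folds),
    matching the convention of reporting mean +- SD across sub-training
    datasets.
    """
    if not results:
        raise ValueError("no results to aggregate")
    arr = np.vstack([m.as_array() for m in results])
    ddof = 1 if len(results) > 1 else 0
    return (
        MetricSet.from_array(arr.mean(axis=0)),
        MetricSet.from_array(arr.std(axis=0, ddof=ddof)),
    )


def write_split_manifest(splits: list[SubTrainingSplit], path: str | Path) -> None:
    """Persist split membership as TSV (id, split index, role) for exact reruns."""
    with open(path, "w") as fh:
        fh.write("id\tsplit\trole\n")
        for s in splits:
            for w in s.positives:
                fh.write(f"{w.id}\t{s.index}\tpositive\n")
            for w in s.negatives:
                fh.write(f"{w.id}\t{s.index}\tnegative\n")


def read_split_manifest(path: str | Path) -> dict[str, list[tuple[int, str]]]:
    """Read a split manifest back into id -> [(split index, role), ...]."""
    out: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: not a split manifest")
        for line in fh:
            rid, idx, role = line.rstrip("\n").split("\t")
            out.setdefault(rid, []).append((int(idx), role))
    return out


def cdhit_reduce(
    fasta_in: str | Path,
    fasta_out: str | Path,
    threshold: float = 0.8,
    executable: str = "cd-hit-est",
) -> Path:
    """Optional shell-out hook to CD-HIT-EST for sequence-redundancy removal.

    Redundancy reduction is an upstream step; this package does not
    reimplement clustering. Raises ``FileNotFoundError`` if the executable
    is not on PATH.
    """
    exe = shutil.which(executable)
    if exe is None:
        raise FileNotFoundError(
            f"{executable} not found on PATH; supply pre-deduplicated input instead"
        )
    subprocess.run(
        [exe, "-i", str(fasta_in), "-o", str(fasta_out), "-c", str(threshold)],
        check=True,
    )
    return Path(fasta_out)
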