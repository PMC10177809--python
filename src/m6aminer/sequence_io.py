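"""Reading, validation and normalization of fixed-length RNA sequence windows.

Every downstream encoder consumes :class:`SequenceWindow` objects: fixed-length
strings over {A, C, G, U} centered (by convention) on a candidate adenosine.
DNA-alphabet input is accepted — T is silently mapped to U and lowercase is
uppercased — but ambiguity codes (N, R, Y, ...) are rejected outright, because
no encoder defines a value for them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

ALPHABET = "ACGU"
DEFAULT_WINDOW_LENGTH = 41

__all__ = [
    "SequenceWindow",
    "LabeledDataset",
    "FastaParseError",
    "WindowValidationError",
    "read_fasta",
    "read_labels",
    "read_fasta_pair",
    "attach_labels",
    "write_fasta",
    "write_labels",
]


class FastaParseError(ValueError):
    """Raised when a sequence file is not parseable FASTA."""


class WindowValidationError(ValueError):
    """Raised when a record violates the window contract (length/alphabet/center)."""


def normalize_bases(raw: str) -> str:
    """Uppercase and map T->U. Does not validate the alphabet."""
    return raw.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class SequenceWindow:
    """A validated fixed-length RNA window.

    Parameters
    ----------
    id : str
        Record identifier (unique within a dataset).
    bases : str
        Normalized sequence over {A, C, G, U}.
    label : int or None
        Optional binary class label (1 = modified site).
    """

    id: str
    bases: str
    label: int | None = None

    @classmethod
    def from_raw(
        cls,
        id: str,
        raw: str,
        window_length: int = DEFAULT_WINDOW_LENGTH,
        center_check: bool = True,
        label: int | None = None,
    ) -> "SequenceWindow":
        """Normalize and validate a raw sequence string.

        Raises
        ------
        WindowValidationError
            On wrong length, non-ACGTU characters, or (if ``center_check``)
            a non-adenosine center base.
        """
        bases = normalize_bases(raw)
        if len(bases) != window_length:
            raise WindowValidationError(
                f"record {id!r}: length {len(bases)} != expected window length {window_length}"
            )
        for offset, b in enumerate(bases):
            if b not in ALPHABET:
                raise WindowValidationError(
                    f"record {id!r}: invalid base {b!r} at offset {offset} (0-based); "
                    "only A/C/G/T/U are accepted"
                )
        if center_check:
            if window_length % 2 == 0:
                raise WindowValidationError(
                    f"record {id!r}: center check requires an odd window length, got {window_length}"
                )
            center = window_length // 2  # 1-based (L+1)/2
            if bases[center] != "A":
                raise WindowValidationError(
                    f"record {id!r}: center base at 1-based position {center + 1} is "
                    f"{bases[center]!r}, expected 'A'"
                )
        return cls(id=id, bases=bases, label=label)

    def __len__(self) -> int:
        return len(self.bases)

    def with_label(self, label: int) -> "SequenceWindow":
        if label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {label!r}")
        return SequenceWindow(self.id, self.bases, label)


@dataclass
class LabeledDataset:
    """A list of labeled windows with cached class counts."""

    windows: list[SequenceWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        for w in self.windows:
            if w.label not in (0, 1):
                raise ValueError(f"window {w.id!r} carries no 0/1 label")

    @property
    def positive_count(self) -> int:
        return sum(1 for w in self.windows if w.label == 1)

    @property
    def negative_count(self) -> int:
        return sum(1 for w in self.windows if w.label == 0)

    @property
    def positives(self) -> list[SequenceWindow]:
        return [w for w in self.windows if w.label == 1]

    @property
    def negatives(self) -> list[SequenceWindow]:
        return [w for w in self.windows if w.label == 0]

    def ids(self) -> list[str]:
        return [w.id for w in self.windows]

    def labels(self) -> dict[str, int]:
        return {w.id: int(w.label) for w in self.windows}

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def read_fasta(
    path: str | Path,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    center_check: bool = True,
) -> list[SequenceWindow]:
    """Read a (multi-record) FASTA file into validated sequence windows.

    Record order is preserved; bases are uppercased and T is mapped to U.

    Raises
    ------
    FastaParseError
        If the file is empty or contains content before the first header.
    WindowValidationError
        If any record fails length/alphabet/center validation.
    """
    path = Path(path)
    if center_check and (window_length < 5 or window_length % 2 == 0):
        raise ValueError(
            f"window_length must be >= 5 and odd when center_check is on, got {window_length}"
        )
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected a '>' FASTA header before sequence data"
                )
            break
        else:
            raise FastaParseError(f"{path}: no FASTA records found")
    windows = [
        SequenceWindow.from_raw(rec.id, str(rec.seq), window_length, center_check)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: set[str] = set()
    for w in windows:
        if w.id in seen:
            raise WindowValidationError(f"duplicate record id {w.id!r} in {path}")
        seen.add(w.id)
    return windows


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` TSV into an id -> {0,1} mapping."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            rid, lab = row[0].strip(), row[1].strip()
            if lab not in ("0", "1"):
                raise ValueError(f"{path}: line {lineno}: label must be 0 or 1, got {lab!r}")
            if rid in labels:
                raise ValueError(f"{path}: duplicate id {rid!r}")
            labels[rid] = int(lab)
    return labels


def attach_labels(
    windows: Sequence[SequenceWindow], labels: Mapping[str, int]
) -> LabeledDataset:
    """Pair windows with an id -> {0,1} mapping into a :class:`LabeledDataset`.

    Raises
    ------
    ValueError
        If any window id is missing from the mapping (all missing ids are
        listed) or if window ids are duplicated.
    """
    seen: set[str] = set()
    for w in windows:
        if w.id in seen:
            raise ValueError(f"duplicate window id {w.id!r}")
        seen.add(w.id)
    missing = [w.id for w in windows if w.id not in labels]
    if missing:
        raise ValueError(f"unlabeled window ids: {missing}")
    return LabeledDataset([w.with_label(int(labels[w.id])) for w in windows])


def read_fasta_pair(
    positives_path: str | Path,
    negatives_path: str | Path,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    center_check: bool = True,
) -> LabeledDataset:
    """Read per-class FASTA files (positives.fa / negatives.fa) into one dataset."""
    pos = read_fasta(positives_path, window_length, center_check)
    neg = read_fasta(negatives_path, window_length, center_check)
    overlap = {w.id for w in pos} & {w.id for w in neg}
    if overlap:
        raise ValueError(f"ids present in both classes: {sorted(overlap)}")
    return LabeledDataset([w.with_label(1) for w in pos] + [w.with_label(0) for w in neg])


def write_fasta(windows: Iterable[SequenceWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.id}\n{w.bases}\n")


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in dataset.windows:
            fh.write(f"{w.id}\t{w.label}\n")
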