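"""Synthetic labeled 41-nt windows with a controllable class signal.

The generator emulates the shape of the real benchmark — fixed-length RNA
windows with an adenosine at the center, a large negative excess
(defaults: 3700 positives, 37,000 negatives) — without attempting to mimic
m6Am biology. Class signal is planted two ways so that both positional and
compositional feature families can detect it:

* a position-weight-matrix motif placed at a fixed offset downstream of the
  center base in positive windows, and
* a mild composition shift of the positive background toward C/G.

``effect_size`` in [0, 1] interpolates both components between the shared
background (0: the classes are identically distributed) and the full
planted signal (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from m6aminer.sequence_io import LabeledDataset, SequenceWindow

ALPHABET = "ACGU"

__all__ = ["GeneratorSpec", "generate", "golden_fixture", "default_motif"]


def default_motif(consensus: str = "GGCAGC", weight: float = 0.85) -> np.ndarray:
    """A PWM concentrating ``weight`` probability on the consensus base at
    each position, the remainder split evenly over the other three."""
    pwm = np.full((len(consensus), 4), (1 - weight) / 3)
    for i, b in enumerate(consensus):
        pwm[i, ALPHABET.index(b)] = weight
    return pwm


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic benchmark.

    Defaults reproduce the benchmark's class sizes (3700 positive /
    37,000 negative 41-nt windows) over a uniform background, with a 6-nt
    motif planted immediately downstream of the center adenosine at
    ``effect_size`` 0.8.
    """

    n_pos: int = 3700
    n_neg: int = 37000
    window_length: int = 41
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: np.ndarray = field(default_factory=default_motif)
    motif_offset: int = 2  # motif start, in positions downstream of center
    composition_shift: float = 0.15  # relative C/G enrichment at effect_size=1
    effect_size: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 non-negative probabilities summing to 1")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.window_length < 5 or self.window_length % 2 == 0:
            raise ValueError("window_length must be odd and >= 5")
        motif = np.asarray(self.motif, dtype=float)
        if motif.ndim != 2 or motif.shape[1] != 4 or np.any(motif < 0):
            raise ValueError("motif must be a (length, 4) probability matrix")
        if not np.allclose(motif.sum(axis=1), 1.0):
            raise ValueError("motif rows must each sum to 1")
        center = self.window_length // 2
        if center + self.motif_offset + len(motif) > self.window_length:
            raise ValueError("motif does not fit inside the window at this offset")


def _class_profile(spec: GeneratorSpec, positive: bool) -> np.ndarray:
    """Per-position base probabilities for one class, (L, 4)."""
    L = spec.window_length
    bg = np.asarray(spec.background, dtype=float)
    profile = np.tile(bg, (L, 1))
    if positive and spec.effect_size > 0:
        e = spec.effect_size
        # compositional shift toward C/G everywhere
        shift = np.array([-1.0, 1.0, 1.0, -1.0]) * spec.composition_shift * e
        shifted = bg * (1.0 + shift)
        profile[:] = shifted / shifted.sum()
        # motif planted downstream of the center
        center = L // 2
        start = center + spec.motif_offset
        motif = np.asarray(spec.motif, dtype=float)
        for i in range(len(motif)):
            profile[start + i] = (1 - e) * profile[start + i] + e * motif[i]
    center = L // 2
    profile[center] = [1.0, 0.0, 0.0, 0.0]  # center base forced to A in both classes
    return profile


def _sample_windows(
    rng: np.random.Generator, profile: np.ndarray, n: int, prefix: str, label: int
) -> list[SequenceWindow]:
    L = profile.shape[0]
    cum = profile.cumsum(axis=1)
    u = rng.random((n, L))
    codes = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    lookup = np.array(list(ALPHABET))
    return [
        SequenceWindow(f"{prefix}{i + 1:05d}", "".join(lookup[row]), label)
        for i, row in enumerate(codes)
    ]


def generate(spec: GeneratorSpec | None = None) -> LabeledDataset:
    """Draw a labeled dataset per the spec; reproducible under ``spec.seed``.

    At ``effect_size`` 0 the positive and negative classes are identically
    distributed, so any downstream classifier is at chance.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    pos = _sample_windows(rng, _class_profile(spec, True), spec.n_pos, "pos", 1)
    neg = _sample_windows(rng, _class_profile(spec, False), spec.n_neg, "neg", 0)
    return LabeledDataset(pos + neg)


# Hand-written 41-nt windows covering the encoder edge cases: homopolymers,
# alternating patterns, a planted motif, and mixed composition. Center base
# (1-based position 21) is A throughout.
_GOLDEN = [
    ("gold01", "A" * 41, 1),
    ("gold02", "U" * 20 + "A" + "U" * 20, 0),
    ("gold03", "G" * 20 + "A" + "G" * 20, 0),
    ("gold04", "C" * 20 + "A" + "C" * 20, 0),
    ("gold05", ("AC" * 21)[:41], 1),
    ("gold06", "GU" * 10 + "A" + "UG" * 10, 0),
    ("gold07", ("ACGU" * 11)[:41], 1),
    ("gold08", "A" * 20 + "A" + "GGCAGC" + "A" * 14, 1),
    ("gold09", "U" * 14 + "GGCAGC" + "A" + "U" * 20, 0),
    ("gold10", ("ACA" * 14)[:41], 1),
    ("gold11", ("GUA" * 14)[:41], 0),
    ("gold12", "ACGUACGUACGUACGUACGUAACGUACGUACGUACGUACGU", 0),
]


def golden_fixture() -> LabeledDataset:
    """Twelve fixed hand-written labeled windows for golden tests; stable
    across releases (tests pin a hash of the sequences)."""
    windows = [
        SequenceWindow.from_raw(rid, seq, window_length=41, center_check=True, label=lab)
        for rid, seq, lab in _GOLDEN
    ]
    return LabeledDataset(windows)
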