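"""Physicochemical property tables for di- and trinucleotides.

The pseudo-composition encoders weight their lag-correlation factors with
physicochemical property vectors. Two default tables ship here and both are
overridable through :class:`~m6aminer.encoders.EncoderConfig`:

* ``DINUCLEOTIDE_PROPERTIES`` — six standard RNA duplex step geometry indices
  (shift, slide, rise, tilt, roll, twist) for the 16 dinucleotides.
* ``TRINUCLEOTIDE_PROPERTIES`` — twelve indices for the 64 trinucleotides,
  built deterministically at import time: the six step indices averaged over
  the two overlapping dinucleotide steps, nearest-neighbour stacking free
  energy summed over the two steps, and five additive per-base descriptors
  (GC count, purine count, amino-group count, summed electron-ion interaction
  potential, summed monophosphate molecular weight).

Property values are always standardized (zero mean, unit variance across the
16 or 64 oligonucleotides) before entering a correlation factor, so only the
relative profile of each index matters.
"""

from __future__ import annotations

from itertools import product

import numpy as np

ALPHABET = "ACGU"

# RNA dinucleotide step parameters (shift/slide/rise in angstroms, tilt/roll/
# twist in degrees), as tabulated for A-form RNA duplex steps.
_DINUC_STEPS: dict[str, tuple[float, float, float, float, float, float]] = {
    #        shift  slide  rise  tilt  roll  twist
    "AA": (-0.08, -1.27, 3.18, -0.8, 7.0, 31.0),
    "AC": (0.23, -1.43, 3.24, 0.8, 4.8, 32.0),
    "AG": (-0.04, -1.50, 3.30, 0.5, 8.5, 30.0),
    "AU": (-0.06, -1.36, 3.24, 1.1, 7.1, 33.0),
    "CA": (0.11, -1.46, 3.09, 1.0, 9.9, 31.0),
    "CC": (-0.01, -1.78, 3.32, 0.3, 8.7, 32.0),
    "CG": (0.30, -1.89, 3.30, -0.1, 12.1, 27.0),
    "CU": (-0.04, -1.50, 3.30, 0.5, 8.5, 30.0),
    "GA": (0.07, -1.70, 3.38, 1.3, 9.4, 32.0),
    "GC": (0.07, -1.39, 3.22, 0.0, 6.1, 35.0),
    "GG": (-0.01, -1.78, 3.32, 0.3, 12.1, 32.0),
    "GU": (0.23, -1.43, 3.24, 0.8, 4.8, 32.0),
    "UA": (-0.02, -1.45, 3.26, -0.2, 10.7, 32.0),
    "UC": (0.07, -1.70, 3.38, 1.3, 9.4, 32.0),
    "UG": (0.11, -1.46, 3.09, 1.0, 9.9, 31.0),
    "UU": (-0.08, -1.27, 3.18, -0.8, 7.0, 31.0),
}

_STEP_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")

DINUCLEOTIDE_PROPERTIES: dict[str, dict[str, float]] = {
    name: {dn: vals[i] for dn, vals in _DINUC_STEPS.items()}
    for i, name in enumerate(_STEP_NAMES)
}

# Nearest-neighbour stacking free energies (kcal/mol, 37 C) for RNA duplex
# steps, mapped onto each dinucleotide via its Watson-Crick duplex step.
_STACKING: dict[str, float] = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

# Additive per-base descriptors.
_BASE_DESCRIPTORS: dict[str, dict[str, float]] = {
    "gc_count": {"A": 0.0, "C": 1.0, "G": 1.0, "U": 0.0},
    "purine_count": {"A": 1.0, "C": 0.0, "G": 1.0, "U": 0.0},
    "amino_count": {"A": 1.0, "C": 1.0, "G": 0.0, "U": 0.0},
    "eiip_sum": {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335},
    "mw_sum": {"A": 347.2, "C": 323.2, "G": 363.2, "U": 324.2},
}


def _build_trinucleotide_properties() -> dict[str, dict[str, float]]:
    tris = ["".join(p) for p in product(ALPHABET, repeat=3)]
    table: dict[str, dict[str, float]] = {}
    for name in _STEP_NAMES:
        dn = DINUCLEOTIDE_PROPERTIES[name]
        table[f"{name}_avg"] = {t: (dn[t[:2]] + dn[t[1:]]) / 2.0 for t in tris}
    table["stacking_energy"] = {t: _STACKING[t[:2]] + _STACKING[t[1:]] for t in tris}
    for name, per_base in _BASE_DESCRIPTORS.items():
        table[name] = {t: sum(per_base[b] for b in t) for t in tris}
    return table


TRINUCLEOTIDE_PROPERTIES: dict[str, dict[str, float]] = _build_trinucleotide_properties()

DEFAULT_DINUCLEOTIDE_INDEX_NAMES = list(DINUCLEOTIDE_PROPERTIES)
DEFAULT_TRINUCLEOTIDE_INDEX_NAMES = list(TRINUCLEOTIDE_PROPERTIES)
assert len(DEFAULT_TRINUCLEOTIDE_INDEX_NAMES) == 12


def standardized_matrix(
    properties: dict[str, dict[str, float]], oligos: list[str]
) -> np.ndarray:
    """Stack property vectors into a (n_properties, n_oligos) array with each
    row standardized to zero mean and unit variance (population formula)."""
    rows = []
    for name, values in properties.items():
        v = np.array([values[o] for o in oligos], dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"property {name!r} is constant and cannot be standardized")
        rows.append((v - v.mean()) / sd)
    return np.vstack(rows)
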