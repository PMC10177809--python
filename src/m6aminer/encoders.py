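"""Nine numeric encoding schemes for fixed-length RNA windows.

Each encoder turns one :class:`~m6aminer.sequence_io.SequenceWindow` into a
:class:`FeatureBlock` — an ordered list of uniquely named real-valued
features. For the default 41-nt window the blocks have these dimensions:

========== ===========================================================  ====
scheme     description                                                  dims
========== ===========================================================  ====
PseEIIP    per-position electron-ion interaction potential + 64          105
           EIIP-weighted trinucleotide frequencies
Hash       sliding 2-mers read as two-digit base-4 numbers                 40
DBE        4-bit positional binary code per overlapping dinucleotide      160
NCP        (ring, amino/keto, H-bond) chemical-property triple per base   123
PseKNC     k-tuple frequencies + lag-correlation factors (k=2, lam=4)      20
DNM        count / mean position / positional variance per dinucleotide    48
Kmer       occurrence counts of all 2-, 3- and 4-mers                     336
SCPseTNC   trinucleotide frequencies (+ optional series correlations)      64
Ksnpf      frequencies of base pairs separated by k=1..5 positions         80
========== ===========================================================  ====

Feature ordering inside every block is strict lexicographic over A<C<G<U —
a package convention imposed for model reproducibility, since the schemes
themselves do not prescribe one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np
import pandas as pd

from m6aminer import physicochem
from m6aminer.sequence_io import SequenceWindow

ALPHABET = "ACGU"
LEX_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Electron-ion interaction potential of the four ribonucleotides.
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335}

#: Base -> quaternary digit used by the hash decimal conversion ('A'-0,
#: 'G'-1, 'C'-2, 'U'-3; note this is NOT the lexicographic index).
HASH_DIGIT = {"A": 0, "G": 1, "C": 2, "U": 3}

#: Dinucleotide binary encoding: two bits per base, chosen so that
#: AA->(0,0,0,0), AU->(0,0,0,1), AC->(0,0,1,0) and GG->(1,1,1,1).
DBE_BITS = {"A": (0, 0), "C": (1, 0), "G": (1, 1), "U": (0, 1)}

#: Nucleotide chemical property triples (ring count, amino/keto, H-bond).
NCP_CODE = {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "U": (0, 0, 1)}

SCHEME_ORDER = ("PseEIIP", "Hash", "DBE", "NCP", "PseKNC", "DNM", "Kmer", "SCPseTNC", "Ksnpf")


@lru_cache(maxsize=None)
def kmer_list(k: int) -> tuple[str, ...]:
    """All 4^k k-mers in lexicographic order over A<C<G<U."""
    return tuple("".join(p) for p in product(ALPHABET, repeat=k))


@dataclass(frozen=True)
class FeatureBlock:
    """Named, ordered numeric features emitted by one encoding scheme."""

    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError(
                f"{self.scheme}: {len(self.names)} names vs {len(self.values)} values"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"{self.scheme}: duplicate feature names")

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


@dataclass(frozen=True)
class EncoderConfig:
    """Tunable parameters of the nine encoders.

    ``psekn_lambda`` must satisfy lambda < L-1 and ``scptnc_lambda`` must
    satisfy lambda < L-3 for a window of length L; omega weights the
    correlation tier against the frequency tier in both pseudo-composition
    encoders. Property tables default to the tables in
    :mod:`m6aminer.physicochem` and can be overridden with any
    ``{index_name: {oligo: value}}`` mapping.
    """

    window_length: int = 41
    psekn_k: int = 2
    psekn_lambda: int = 4
    psekn_omega: float = 0.1
    psekn_properties: dict[str, dict[str, float]] | None = None
    scptnc_lambda: int = 0
    scptnc_omega: float = 0.1
    scptnc_properties: dict[str, dict[str, float]] | None = None
    kmer_ks: tuple[int, ...] = (2, 3, 4)
    ksnpf_max_gap: int = 5
    hash_k: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.psekn_omega <= 1.0 or not 0.0 <= self.scptnc_omega <= 1.0:
            raise ValueError("omega weights must lie in [0, 1]")
        if self.psekn_lambda < 0 or self.scptnc_lambda < 0:
            raise ValueError("lambda must be non-negative")

    def dinuc_properties(self) -> dict[str, dict[str, float]]:
        return self.psekn_properties or physicochem.DINUCLEOTIDE_PROPERTIES

    def trinuc_properties(self) -> dict[str, dict[str, float]]:
        return self.scptnc_properties or physicochem.TRINUCLEOTIDE_PROPERTIES

    def config_hash(self) -> str:
        import hashlib
        import json

        payload = {
            "window_length": self.window_length,
            "psekn_k": self.psekn_k,
            "psekn_lambda": self.psekn_lambda,
            "psekn_omega": self.psekn_omega,
            "psekn_properties": self.dinuc_properties(),
            "scptnc_lambda": self.scptnc_lambda,
            "scptnc_omega": self.scptnc_omega,
            "scptnc_properties": self.trinuc_properties(),
            "kmer_ks": list(self.kmer_ks),
            "ksnpf_max_gap": self.ksnpf_max_gap,
            "hash_k": self.hash_k,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _codes(w: SequenceWindow) -> np.ndarray:
    return np.fromiter((LEX_INDEX[b] for b in w.bases), dtype=np.int64, count=len(w))


def _kmer_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """Lexicographic id of every overlapping k-mer (base-4 over A<C<G<U)."""
    n = len(codes) - k + 1
    if n <= 0:
        raise ValueError(f"k={k} exceeds window length {len(codes)}")
    ids = np.zeros(n, dtype=np.int64)
    for j in range(k):
        ids = ids * 4 + codes[j : j + n]
    return ids


def _kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(_kmer_ids(codes, k), minlength=4**k).astype(float)


def encode_pseeiip(w: SequenceWindow) -> FeatureBlock:
    """Pseudo electron-ion interaction potential: L per-position EIIP values
    followed by EIIP_xyz * f_xyz for the 64 trinucleotides, where
    EIIP_xyz = EIIP_x + EIIP_y + EIIP_z and f_xyz = N_xyz / (L - 2)."""
    L = len(w)
    per_pos = np.array([EIIP[b] for b in w.bases])
    counts = _kmer_counts(_codes(w), 3)
    freqs = counts / (L - 2)
    tri = kmer_list(3)
    tri_eiip = np.array([EIIP[t[0]] + EIIP[t[1]] + EIIP[t[2]] for t in tri])
    names = tuple(f"PseEIIP:pos{i + 1:02d}" for i in range(L)) + tuple(
        f"PseEIIP:{t}" for t in tri
    )
    return FeatureBlock("PseEIIP", names, np.concatenate([per_pos, tri_eiip * freqs]))


def encode_hash(w: SequenceWindow, k: int = 2) -> FeatureBlock:
    """Hash decimal conversion: each sliding k-mer read as a k-digit base-4
    number with digits A=0, G=1, C=2, U=3; emits L-k+1 decimals."""
    L = len(w)
    if k < 1 or k > L:
        raise ValueError(f"hash k must be in [1, {L}], got {k}")
    digits = np.fromiter((HASH_DIGIT[b] for b in w.bases), dtype=np.int64, count=L)
    n = L - k + 1
    vals = np.zeros(n, dtype=np.int64)
    for j in range(k):
        vals = vals * 4 + digits[j : j + n]
    names = tuple(f"Hash:pos{i + 1:02d}" for i in range(n))
    return FeatureBlock("Hash", names, vals.astype(float))


def encode_dbe(w: SequenceWindow) -> FeatureBlock:
    """Dinucleotide binary encoding: 4 bits (2 per base) for each of the
    L-1 overlapping dinucleotides, flattened in sequence order."""
    bits: list[float] = []
    names: list[str] = []
    for i in range(len(w) - 1):
        a, b = w.bases[i], w.bases[i + 1]
        bits.extend(DBE_BITS[a] + DBE_BITS[b])
        names.extend(f"DBE:pos{i + 1:02d}:b{j}" for j in range(4))
    return FeatureBlock("DBE", tuple(names), np.array(bits))


def encode_ncp(w: SequenceWindow) -> FeatureBlock:
    """Nucleotide chemical property: the (x, y, z) triple per position.

    x separates purines (two rings: A, G) from pyrimidines, y amino (A, C)
    from keto (G, U) groups, z weak (A, U) from strong (C, G) hydrogen
    bonding."""
    vals: list[float] = []
    names: list[str] = []
    for i, b in enumerate(w.bases):
        vals.extend(NCP_CODE[b])
        names.extend(f"NCP:pos{i + 1:02d}:{c}" for c in "xyz")
    return FeatureBlock("NCP", tuple(names), np.array(vals))


def _correlation_factors_psekn(
    codes: np.ndarray, lam: int, prop_matrix: np.ndarray
) -> np.ndarray:
    """Tier-j correlation factors theta_j, j = 1..lam, from the mean squared
    property difference between dinucleotides j steps apart."""
    L = len(codes)
    dinuc_ids = codes[:-1] * 4 + codes[1:]  # L-1 dinucleotides
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        n_pairs = L - j - 1
        if n_pairs <= 0:
            raise ValueError(f"lambda={lam} too large for window length {L}")
        a = prop_matrix[:, dinuc_ids[:n_pairs]]
        b = prop_matrix[:, dinuc_ids[j : j + n_pairs]]
        # Phi = mean over properties of squared difference
        theta[j - 1] = np.mean((a - b) ** 2, axis=0).sum() / n_pairs
    return theta


def encode_psekn(w: SequenceWindow, cfg: EncoderConfig) -> FeatureBlock:
    """Pseudo k-tuple nucleotide composition.

    The first 4^k components are normalized k-tuple frequencies, the last
    ``lambda`` components are omega-weighted dinucleotide correlation
    factors; all components share one denominator so the block sums to 1.
    """
    L = len(w)
    k, lam, omega = cfg.psekn_k, cfg.psekn_lambda, cfg.psekn_omega
    if lam >= L - 1:
        raise ValueError(f"psekn_lambda must satisfy lambda < L-1 = {L - 1}, got {lam}")
    props = cfg.dinuc_properties()
    if not props:
        raise ValueError("PseKNC requires a non-empty dinucleotide property table")
    codes = _codes(w)
    freqs = _kmer_counts(codes, k)
    freqs = freqs / freqs.sum()
    if lam > 0:
        prop_matrix = physicochem.standardized_matrix(props, list(kmer_list(2)))
        theta = _correlation_factors_psekn(codes, lam, prop_matrix)
    else:
        theta = np.empty(0)
    denom = freqs.sum() + omega * theta.sum()
    values = np.concatenate([freqs, omega * theta]) / denom
    names = tuple(f"PseKNC:f:{m}" for m in kmer_list(k)) + tuple(
        f"PseKNC:theta{j + 1}" for j in range(lam)
    )
    return FeatureBlock("PseKNC", names, values)


def encode_dnm(w: SequenceWindow) -> FeatureBlock:
    """Dinucleotide numerical mapping: for each of the 16 dinucleotides the
    occurrence count n, the mean 1-based occurrence position u, and the
    normalized positional variance D2 = sum((i-u)^2) / (n * (m-1)).

    A dinucleotide that never occurs gets (0, 0, 0)."""
    m = len(w)
    codes = _codes(w)
    dinuc_ids = codes[:-1] * 4 + codes[1:]
    positions = np.arange(1, m, dtype=float)  # 1-based position of each dinucleotide
    names: list[str] = []
    vals: list[float] = []
    for d_id, dn in enumerate(kmer_list(2)):
        pos = positions[dinuc_ids == d_id]
        n = float(len(pos))
        if n == 0:
            u = d2 = 0.0
        else:
            u = pos.mean()
            d2 = float(((pos - u) ** 2).sum()) / (n * (m - 1))
        names.extend((f"DNM:{dn}:n", f"DNM:{dn}:u", f"DNM:{dn}:D2"))
        vals.extend((n, u, d2))
    return FeatureBlock("DNM", tuple(names), np.array(vals))


def encode_kmer(w: SequenceWindow, ks: tuple[int, ...] = (2, 3, 4)) -> FeatureBlock:
    """Occurrence counts of every k-mer over sliding windows, concatenated
    over the configured k values (lexicographic within each k)."""
    L = len(w)
    if max(ks) > L:
        raise ValueError(f"k={max(ks)} exceeds window length {L}")
    codes = _codes(w)
    names: list[str] = []
    parts: list[np.ndarray] = []
    for k in ks:
        parts.append(_kmer_counts(codes, k))
        names.extend(f"Kmer:k{k}:{m}" for m in kmer_list(k))
    return FeatureBlock("Kmer", tuple(names), np.concatenate(parts))


def encode_scptnc(w: SequenceWindow, cfg: EncoderConfig) -> FeatureBlock:
    """Series correlation pseudo trinucleotide composition.

    The first 64 components are normalized trinucleotide frequencies; with
    ``scptnc_lambda`` > 0 one correlation factor per (lag m, property xi)
    pair is appended, built from products of standardized property values of
    trinucleotides m steps apart. The default configuration (lambda = 0)
    emits exactly the 64 frequency components.
    """
    L = len(w)
    lam, omega = cfg.scptnc_lambda, cfg.scptnc_omega
    if lam >= L - 3:
        raise ValueError(f"scptnc_lambda must satisfy lambda < L-3 = {L - 3}, got {lam}")
    codes = _codes(w)
    freqs = _kmer_counts(codes, 3)
    freqs = freqs / freqs.sum()
    names = [f"SCPseTNC:f:{t}" for t in kmer_list(3)]
    if lam > 0:
        props = cfg.trinuc_properties()
        if not props:
            raise ValueError("SCPseTNC with lambda > 0 requires trinucleotide properties")
        prop_names = list(props)
        prop_matrix = physicochem.standardized_matrix(props, list(kmer_list(3)))
        tri_ids = _kmer_ids(codes, 3)
        theta: list[float] = []
        for m_lag in range(1, lam + 1):
            n_terms = L - m_lag - 3
            if n_terms <= 0:
                raise ValueError(f"lag {m_lag} too large for window length {L}")
            a = prop_matrix[:, tri_ids[:n_terms]]
            b = prop_matrix[:, tri_ids[m_lag : m_lag + n_terms]]
            per_prop = (a * b).sum(axis=1) / n_terms
            theta.extend(per_prop)
            names.extend(f"SCPseTNC:theta:m{m_lag}:{p}" for p in prop_names)
        theta_arr = np.array(theta)
        denom = freqs.sum() + omega * theta_arr.sum()
        values = np.concatenate([freqs, omega * theta_arr]) / denom
    else:
        values = freqs
    return FeatureBlock("SCPseTNC", tuple(names), values)


def encode_ksnpf(w: SequenceWindow, max_gap: int = 5) -> FeatureBlock:
    """K-spaced nucleotide pair frequency: for each gap k = 1..max_gap and
    ordered pair (n1, n2), the count of positions i with bases
    (i, i+k+1) = (n1, n2), divided by L-k-1."""
    L = len(w)
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if L <= max_gap + 1:
        raise ValueError(f"window length {L} too short for max_gap={max_gap}")
    codes = _codes(w)
    names: list[str] = []
    vals: list[float] = []
    for k in range(1, max_gap + 1):
        n_pairs = L - k - 1
        pair_ids = codes[:n_pairs] * 4 + codes[k + 1 : k + 1 + n_pairs]
        counts = np.bincount(pair_ids, minlength=16).astype(float)
        for pair, c in zip(kmer_list(2), counts):
            names.append(f"Ksnpf:{pair[0]}_gap{k}_{pair[1]}")
            vals.append(c / n_pairs)
    return FeatureBlock("Ksnpf", tuple(names), np.array(vals))


def encode_all(w: SequenceWindow, cfg: EncoderConfig | None = None) -> FeatureBlock:
    """Concatenate all nine blocks in the fixed scheme order.

    On a 41-nt window with the default configuration this yields
    105 + 40 + 160 + 123 + 20 + 48 + 336 + 64 + 80 = 976 features.
    """
    cfg = cfg or EncoderConfig(window_length=len(w))
    blocks = [
        encode_pseeiip(w),
        encode_hash(w, cfg.hash_k),
        encode_dbe(w),
        encode_ncp(w),
        encode_psekn(w, cfg),
        encode_dnm(w),
        encode_kmer(w, cfg.kmer_ks),
        encode_scptnc(w, cfg),
        encode_ksnpf(w, cfg.ksnpf_max_gap),
    ]
    names: tuple[str, ...] = ()
    for b in blocks:
        names += b.names
    if len(set(names)) != len(names):
        raise RuntimeError("feature names are not globally unique across blocks")
    return FeatureBlock("ALL", names, np.concatenate([b.values for b in blocks]))


def encode_matrix(
    windows, cfg: EncoderConfig | None = None
) -> pd.DataFrame:
    """Encode a collection of windows into a (n_windows, n_features)
    DataFrame indexed by window id with globally unique feature columns."""
    windows = list(windows)
    if not windows:
        raise ValueError("no windows to encode")
    cfg = cfg or EncoderConfig(window_length=len(windows[0]))
    first = encode_all(windows[0], cfg)
    out = np.empty((len(windows), len(first)))
    out[0] = first.values
    for i, w in enumerate(windows[1:], start=1):
        out[i] = encode_all(w, cfg).values
    return pd.DataFrame(out, index=[w.id for w in windows], columns=list(first.names))


def write_matrix(X: pd.DataFrame, path, sep: str = "\t") -> None:
    """Export a feature matrix with a header of feature names and one row
    per window id."""
    X.to_csv(path, sep=sep, index_label="id")


def cached_encode_matrix(windows, cfg: EncoderConfig, cache_dir) -> pd.DataFrame:
    """Encode with a joblib-backed on-disk cache keyed by (config hash,
    input hash). Useful when iterating on selection/modeling over a fixed
    feature matrix."""
    import hashlib
    from pathlib import Path

    import joblib

    windows = list(windows)
    input_hash = hashlib.sha256(
        "".join(f"{w.id}:{w.bases};" for w in windows).encode()
    ).hexdigest()[:16]
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = cache_dir / f"features-{cfg.config_hash()}-{input_hash}.joblib"
    if key.exists():
        return joblib.load(key)
    X = encode_matrix(windows, cfg)
    joblib.dump(X, key)
    return X
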