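"""Encoder unit tests: golden values, dimensional contracts across window
lengths, brute-force counting oracles, and permutation-sensitivity checks."""

from itertools import product

import numpy as np
import pytest

from conftest import random_window
from m6aminer.encoders import (
    DBE_BITS,
    EIIP,
    EncoderConfig,
    NCP_CODE,
    encode_all,
    encode_dbe,
    encode_dnm,
    encode_hash,
    encode_kmer,
    encode_ksnpf,
    encode_ncp,
    encode_matrix,
    encode_pseeiip,
    encode_psekn,
    encode_scptnc,
    kmer_list,
)
from m6aminer.sequence_io import SequenceWindow

ALPHABET = "ACGU"


# ---------------------------------------------------------------- oracles
def count_kmer(seq: str, kmer: str) -> int:
    """Naive overlapping substring count."""
    k = len(kmer)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == kmer)


def count_gapped_pair(seq: str, n1: str, n2: str, gap: int) -> int:
    return sum(
        1
        for i in range(len(seq) - gap - 1)
        if seq[i] == n1 and seq[i + gap + 1] == n2
    )


# ---------------------------------------------------------- golden values
def test_eiip_per_base_values():
    assert EIIP == {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335}


def test_pseeiip_poly_a(poly_a):
    block = encode_pseeiip(poly_a)
    vals = dict(zip(block.names, block.values))
    assert vals["PseEIIP:AAA"] == pytest.approx(3 * 0.1260)  # f_AAA = 1
    others = [v for n, v in vals.items() if n.startswith("PseEIIP:") and
              not n.startswith("PseEIIP:pos") and n != "PseEIIP:AAA"]
    assert all(v == 0 for v in others)


def test_pseeiip_position_value_for_leading_g():
    w = SequenceWindow("g", "G" + "A" * 40)
    block = encode_pseeiip(w)
    assert block.values[0] == pytest.approx(0.0806)


def test_hash_digit_examples():
    # AA -> 0, GU -> 4*1+3 = 7 under the A-0 G-1 C-2 U-3 digit map
    w = SequenceWindow("x", "AAGU" + "A" * 37)
    block = encode_hash(w, k=2)
    assert block.values[0] == 0  # AA
    assert block.values[2] == 7  # GU


def test_dbe_printed_codes():
    def code(dinuc):
        w = SequenceWindow("x", dinuc + "A" * 39)
        return tuple(encode_dbe(w).values[:4].astype(int))

    assert code("AA") == (0, 0, 0, 0)
    assert code("AU") == (0, 0, 0, 1)  # AT in DNA spelling
    assert code("AC") == (0, 0, 1, 0)
    assert code("GG") == (1, 1, 1, 1)


def test_ncp_printed_codes():
    assert NCP_CODE == {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "U": (0, 0, 1)}
    # x distinguishes purines from pyrimidines
    for b, (x, _, _) in NCP_CODE.items():
        assert x == (1 if b in "AG" else 0)


def test_dnm_poly_a(poly_a):
    block = encode_dnm(poly_a)
    vals = dict(zip(block.names, block.values))
    assert vals["DNM:AA:n"] == 40
    assert vals["DNM:AA:u"] == pytest.approx(20.5)
    # absent dinucleotide convention
    assert (vals["DNM:CG:n"], vals["DNM:CG:u"], vals["DNM:CG:D2"]) == (0, 0, 0)


def test_kmer_poly_a(poly_a):
    block = encode_kmer(poly_a)
    vals = dict(zip(block.names, block.values))
    assert vals["Kmer:k4:AAAA"] == 38
    assert sum(v for n, v in vals.items() if n.startswith("Kmer:k4:")) == 38


def test_ksnpf_poly_a(poly_a):
    block = encode_ksnpf(poly_a)
    vals = dict(zip(block.names, block.values))
    assert vals["Ksnpf:A_gap1_A"] == pytest.approx(1.0)  # 39/39
    assert vals["Ksnpf:C_gap1_C"] == 0.0


def test_psekn_poly_a_reduces_to_frequencies(poly_a):
    block = encode_psekn(poly_a, EncoderConfig())
    vals = dict(zip(block.names, block.values))
    # all dinucleotides identical => Phi = 0 => every theta = 0
    assert all(vals[f"PseKNC:theta{j}"] == 0 for j in (1, 2, 3, 4))
    assert vals["PseKNC:f:AA"] == pytest.approx(1.0)


def test_scptnc_poly_a_constant_correlations(poly_a):
    cfg = EncoderConfig(scptnc_lambda=3)
    block = encode_scptnc(poly_a, cfg)
    theta = {n: v for n, v in zip(block.names, block.values) if "theta" in n}
    assert len(theta) == 3 * 12
    # constant trinucleotide => all thetas equal within a property
    by_prop = {}
    for name, v in theta.items():
        by_prop.setdefault(name.split(":")[-1], []).append(v)
    for vals in by_prop.values():
        assert np.allclose(vals, vals[0])


# ------------------------------------------------- dimensional contracts
EXPECTED_41 = {
    "PseEIIP": 105,
    "Hash": 40,
    "DBE": 160,
    "NCP": 123,
    "DNM": 48,
    "Kmer": 336,
    "SCPseTNC": 64,
    "Ksnpf": 80,
}


def test_default_dims_on_41nt(poly_a):
    cfg = EncoderConfig()
    dims = {
        "PseEIIP": len(encode_pseeiip(poly_a)),
        "Hash": len(encode_hash(poly_a)),
        "DBE": len(encode_dbe(poly_a)),
        "NCP": len(encode_ncp(poly_a)),
        "DNM": len(encode_dnm(poly_a)),
        "Kmer": len(encode_kmer(poly_a)),
        "SCPseTNC": len(encode_scptnc(poly_a, cfg)),
        "Ksnpf": len(encode_ksnpf(poly_a)),
    }
    assert dims == EXPECTED_41
    assert len(encode_psekn(poly_a, cfg)) == 4**cfg.psekn_k + cfg.psekn_lambda


@pytest.mark.parametrize("L", [8, 9, 13, 21, 41, 61])
def test_dim_contracts_arbitrary_lengths(L):
    rng = np.random.default_rng(L)
    w = random_window(rng, L)
    cfg = EncoderConfig(window_length=L, psekn_lambda=2, scptnc_lambda=1, kmer_ks=(2, 3))
    assert len(encode_pseeiip(w)) == L + 64
    assert len(encode_hash(w, 2)) == L - 1
    assert len(encode_dbe(w)) == 4 * (L - 1)
    assert len(encode_ncp(w)) == 3 * L
    assert len(encode_psekn(w, cfg)) == 16 + 2
    assert len(encode_dnm(w)) == 48
    assert len(encode_kmer(w, (2, 3))) == 16 + 64
    assert len(encode_scptnc(w, cfg)) == 64 + 1 * 12
    assert len(encode_ksnpf(w, 5)) == 80


def test_lambda_bounds_enforced():
    w = SequenceWindow("x", "ACGUACGUA")  # L = 9
    with pytest.raises(ValueError):
        encode_psekn(w, EncoderConfig(psekn_lambda=8))
    with pytest.raises(ValueError):
        encode_scptnc(w, EncoderConfig(scptnc_lambda=6))
    with pytest.raises(ValueError):
        encode_hash(w, k=10)


# ------------------------------------------------ brute-force equivalence
def test_counting_encoders_match_bruteforce():
    rng = np.random.default_rng(42)
    for trial in range(200):
        L = int(rng.integers(8, 16))
        w = random_window(rng, L, f"r{trial}")
        seq = w.bases

        kb = encode_kmer(w, (2, 3))
        vals = dict(zip(kb.names, kb.values))
        for m in kmer_list(2):
            assert vals[f"Kmer:k2:{m}"] == count_kmer(seq, m)
        for m in kmer_list(3):
            assert vals[f"Kmer:k3:{m}"] == count_kmer(seq, m)

        pe = dict(zip(*[encode_pseeiip(w).names, encode_pseeiip(w).values]))
        for m in kmer_list(3):
            expect = (EIIP[m[0]] + EIIP[m[1]] + EIIP[m[2]]) * count_kmer(seq, m) / (L - 2)
            assert pe[f"PseEIIP:{m}"] == pytest.approx(expect)

        ks = dict(zip(*[encode_ksnpf(w, 3).names, encode_ksnpf(w, 3).values]))
        for gap in (1, 2, 3):
            for n1, n2 in product(ALPHABET, repeat=2):
                expect = count_gapped_pair(seq, n1, n2, gap) / (L - gap - 1)
                assert ks[f"Ksnpf:{n1}_gap{gap}_{n2}"] == pytest.approx(expect)

        dn = dict(zip(*[encode_dnm(w).names, encode_dnm(w).values]))
        for m in kmer_list(2):
            positions = [i + 1 for i in range(L - 1) if seq[i : i + 2] == m]
            n = len(positions)
            assert dn[f"DNM:{m}:n"] == n
            if n:
                u = sum(positions) / n
                d2 = sum((p - u) ** 2 for p in positions) / (n * (L - 1))
                assert dn[f"DNM:{m}:u"] == pytest.approx(u)
                assert dn[f"DNM:{m}:D2"] == pytest.approx(d2)


def test_psekn_components_sum_to_one():
    rng = np.random.default_rng(7)
    cfg = EncoderConfig(psekn_lambda=6)
    for trial in range(20):
        w = random_window(rng, 41, f"p{trial}")
        assert encode_psekn(w, cfg).values.sum() == pytest.approx(1.0)


def test_scptnc_lambda0_is_normalized_frequencies():
    rng = np.random.default_rng(8)
    w = random_window(rng, 41)
    block = encode_scptnc(w, EncoderConfig())
    assert block.values.sum() == pytest.approx(1.0)
    assert all(0 <= v <= 1 for v in block.values)


# ------------------------------------------------ permutation sensitivity
def _shuffled(w: SequenceWindow, seed: int) -> SequenceWindow:
    rng = np.random.default_rng(seed)
    bases = list(w.bases)
    while True:
        rng.shuffle(bases)
        if "".join(bases) != w.bases:
            return SequenceWindow(w.id + "_shuf", "".join(bases))


def test_composition_blocks_permutation_invariant_positional_not():
    rng = np.random.default_rng(99)
    w = random_window(rng, 41, "perm")
    s = _shuffled(w, 1)
    # composition-only: k-mer counts of order 1 and the EIIP product part
    assert np.allclose(
        encode_kmer(w, (1,)).values, encode_kmer(s, (1,)).values
    )
    pe_w, pe_s = encode_pseeiip(w), encode_pseeiip(s)
    # per-position part differs, product part over 1-mers... use NCP/DBE/Hash
    assert not np.allclose(encode_ncp(w).values, encode_ncp(s).values)
    assert not np.allclose(encode_dbe(w).values, encode_dbe(s).values)
    assert not np.allclose(encode_hash(w).values, encode_hash(s).values)
    assert not np.allclose(pe_w.values[:41], pe_s.values[:41])


# --------------------------------------------------------- concatenation
def test_encode_all_deterministic_and_unique(poly_a):
    a, b = encode_all(poly_a), encode_all(poly_a)
    assert a.names == b.names
    assert np.array_equal(a.values, b.values)
    assert len(set(a.names)) == len(a.names)


def test_encode_all_total_default(poly_a):
    # 105+40+160+123+48+336+80 = 892 unambiguous, + PseKNC(20) + SCPseTNC(64)
    assert len(encode_all(poly_a)) == 892 + 20 + 64


def test_dna_spelling_gives_identical_vector():
    rna = SequenceWindow.from_raw("r", "ACGU" * 10 + "A", center_check=False)
    dna = SequenceWindow.from_raw("d", "ACGT" * 10 + "A", center_check=False)
    assert np.array_equal(encode_all(rna).values, encode_all(dna).values)


def test_encode_matrix_shape_and_index(golden):
    X = encode_matrix(golden.windows)
    assert X.shape == (12, 976)
    assert list(X.index) == [w.id for w in golden.windows]
    assert not X.isna().any().any()


def test_frequency_features_bounded(golden):
    X = encode_matrix(golden.windows)
    for prefix in ("PseKNC:", "SCPseTNC:f:", "Ksnpf:"):
        cols = [c for c in X.columns if c.startswith(prefix)]
        sub = X[cols].values
        assert sub.min() >= 0 and sub.max() <= 1
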