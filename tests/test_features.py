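import itertools

import numpy as np
import pytest

from conftest import random_sequence
from lncrnapred.errors import ValidationError
from lncrnapred.features import (
    FEATURE_NAMES,
    extract_features,
    kmer_frequencies,
    max_orf,
    power_spectrum,
    rmax_orf,
    snr,
    voss_mapping,
)
from lncrnapred.sequence_io import Transcript

# ---------------------------------------------------------------------------
# independent oracles


def dft_power_oracle(seq: str) -> np.ndarray:
    """Direct O(N^2) DFT summation of the four indicator tracks."""
    n = len(seq)
    P = np.zeros(n)
    for base in "ACGT":
        u = np.array([1.0 if ch == base else 0.0 for ch in seq])
        for k in range(n):
            re = sum(u[m] * np.cos(2 * np.pi * m * k / n) for m in range(n))
            im = sum(-u[m] * np.sin(2 * np.pi * m * k / n) for m in range(n))
            P[k] += re**2 + im**2
    return P


def dft_power_oracle_fastish(seq: str) -> np.ndarray:
    """Same direct summation vectorised over the N x N phase matrix."""
    n = len(seq)
    m, k = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    W = np.exp(-2j * np.pi * m * k / n)
    P = np.zeros(n)
    for base in "ACGT":
        u = np.array([1.0 if ch == base else 0.0 for ch in seq])
        U = u @ W
        P += np.abs(U) ** 2
    return P


def snr_oracle(seq: str) -> float:
    P = dft_power_oracle_fastish(seq)
    n = len(seq)
    return P[int(round(n / 3))] / (P.sum() / n)


def max_orf_oracle(seq: str) -> int:
    """Enumerate every ATG in every forward frame; walk codons to first stop."""
    best = 0
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for j in range(start, len(seq) - 2, 3):
            if seq[j : j + 3] in ("TAA", "TAG", "TGA"):
                best = max(best, j + 3 - start)
                break
    return best


# ---------------------------------------------------------------------------


class TestVossMapping:
    def test_published_worked_example(self):
        tracks = voss_mapping("ATCTCACTGGT")
        assert tracks.u_T.tolist() == [0, 1, 0, 1, 0, 0, 0, 1, 0, 0, 1]
        assert tracks.u_A.tolist() == [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0]
        assert tracks.u_C.tolist() == [0, 0, 1, 0, 1, 0, 1, 0, 0, 0, 0]
        assert tracks.u_G.tolist() == [0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0]

    def test_homopolymer(self):
        tracks = voss_mapping("AAAA")
        assert tracks.u_A.tolist() == [1, 1, 1, 1]
        assert tracks.u_C.sum() == tracks.u_G.sum() == tracks.u_T.sum() == 0

    def test_tracks_partition_every_position(self):
        rng = np.random.default_rng(0)
        seq = random_sequence(rng, 137)
        assert (voss_mapping(seq).as_matrix().sum(axis=0) == 1).all()

    def test_disallowed_character_names_position(self):
        with pytest.raises(ValidationError, match="position 2"):
            voss_mapping("ACNA")


class TestPowerSpectrum:
    def test_poly_a_concentrates_at_zero(self):
        ps = power_spectrum(voss_mapping("A" * 300))
        assert ps.P[0] == pytest.approx(90000)
        assert np.allclose(ps.P[1:], 0, atol=1e-6)

    def test_acgt_flat_spectrum_matches_slow_oracle(self):
        ps = power_spectrum(voss_mapping("ACGT"))
        assert np.allclose(ps.P, 4.0)
        assert np.allclose(ps.P, dft_power_oracle("ACGT"), atol=1e-9)

    @pytest.mark.parametrize("n", [7, 50, 121, 300])
    def test_parseval_total_power_is_n_squared(self, n):
        rng = np.random.default_rng(n)
        ps = power_spectrum(voss_mapping(random_sequence(rng, n)))
        assert ps.P.sum() == pytest.approx(n**2, rel=1e-6)


class TestSNR:
    @pytest.mark.parametrize(
        "seq,expected",
        [("A" * 300, 0.0), ("ACG" * 100, 100.0), ("ACGT", 1.0)],
    )
    def test_analytic_values(self, seq, expected):
        assert snr(seq) == pytest.approx(expected, abs=1e-9)

    def test_fast_transform_matches_direct_dft_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(50, 1201))
            seq = random_sequence(rng, n)
            assert snr(seq) == pytest.approx(snr_oracle(seq), abs=1e-8)

    def test_spectrum_mean_equals_length(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 900))
            seq = random_sequence(rng, n)
            ps = power_spectrum(voss_mapping(seq))
            assert ps.P.sum() / n == pytest.approx(n, rel=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            snr("AC")


class TestMaxORF:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGTAA", 6),
            ("AATGAAATAGC", 9),
            ("CCCCCC", 0),
            ("ATGAAA", 0),          # no in-frame stop: no ORF
            ("ATGATGAAATAA", 12),   # earliest ATG wins for a shared stop
        ],
    )
    def test_known_cases(self, seq, expected):
        assert max_orf(seq) == expected

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            n = int(rng.integers(30, 2001))
            seq = random_sequence(rng, n)
            got = max_orf(seq)
            assert got == max_orf_oracle(seq)
            assert got == 0 or (got % 3 == 0 and got >= 6)


class TestRMaxORF:
    @pytest.mark.parametrize(
        "orf,length,expected",
        [(6, 6, 1.0), (0, 500, 0.0), (9, 11, pytest.approx(0.8182, abs=1e-4))],
    )
    def test_ratio(self, orf, length, expected):
        assert rmax_orf(orf, length) == expected

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            rmax_orf(0, 0)


class TestKmerFrequencies:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("ACGT", 1, [0.25, 0.25, 0.25, 0.25]),
            ("AAAA", 2, [1.0] + [0.0] * 15),
        ],
    )
    def test_simple_cases(self, seq, k, expected):
        assert np.allclose(kmer_frequencies(seq, k), expected)

    def test_overlapping_window_denominator(self):
        freqs = kmer_frequencies("ACGA", 2)
        names = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        got = dict(zip(names, freqs))
        assert got["AC"] == got["CG"] == got["GA"] == pytest.approx(1 / 3)
        assert sum(freqs) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_blocks_sum_to_one(self, k):
        rng = np.random.default_rng(k)
        seq = random_sequence(rng, 211)
        assert kmer_frequencies(seq, k).sum() == pytest.approx(1.0, abs=1e-9)

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValidationError):
            kmer_frequencies("AC", 3)


class TestExtractFeatures:
    def test_exactly_89_named_features_in_canonical_order(self):
        rng = np.random.default_rng(1)
        vec = extract_features(random_sequence(rng, 400))
        assert list(vec.index) == FEATURE_NAMES
        assert len(vec) == 89

    def test_consistency_with_single_feature_operations(self):
        seq = "ATGTAA" + "CGCA" * 80
        vec = extract_features(Transcript("t", seq))
        assert vec["MaxORF"] == max_orf(seq)
        assert vec["RMaxORF"] == pytest.approx(max_orf(seq) / len(seq))
        assert vec["SNR"] == pytest.approx(snr(seq))
        assert vec["Length"] == len(seq)

    def test_homopolymer_gc_and_snr(self):
        vec = extract_features("G" * 300)
        assert vec["(G+C)%"] == 1.0
        assert vec["SNR"] == 0.0

    def test_gc_feature_distinct_from_gc_dinucleotide(self):
        vec = extract_features("GC" * 150)
        assert vec["(G+C)%"] == 1.0
        assert vec["GC%"] == pytest.approx(150 / 299)

    def test_deterministic_and_order_independent(self, small_dataset):
        batch = small_dataset[:10]
        a = [extract_features(t) for t in batch]
        b = [extract_features(t) for t in reversed(batch)]
        for va, vb in zip(a, reversed(b)):
            assert (va == vb).all()

    def test_synthetic_classes_separate_on_snr_and_maxorf(self, small_features):
        X, y = small_features
        coding = X.loc[(y == "CODING").to_numpy()]
        noncoding = X.loc[(y == "NONCODING").to_numpy()]
        assert coding["SNR"].mean() > noncoding["SNR"].mean()
        assert coding["MaxORF"].mean() > noncoding["MaxORF"].mean()
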