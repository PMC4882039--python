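"""The 89-dimensional hybrid feature vector.

Features, in canonical order:

* ``MaxORF`` — length (nt, stop codon included) of the longest open reading
  frame across the three forward frames; 0 when no ATG..stop span exists.
* ``RMaxORF`` — MaxORF divided by sequence length, in [0, 1].
* ``SNR`` — period-3 signal-to-noise ratio: the power spectrum of the four
  Voss indicator tracks evaluated at the N/3 bin, divided by the spectrum
  mean.  Coding sequences show a period-3 peak because codon-position
  nucleotide usage is biased; non-coding sequences do not.
* ``Length`` — sequence length N (nt).
* ``(G+C)%`` — fraction of G or C bases.
* 4 mononucleotide, 16 dinucleotide and 64 trinucleotide frequencies over
  overlapping windows, each block summing to one, in lexicographic
  A < C < G < T order.

By Parseval's identity the total spectral power equals N^2, so the spectrum
mean is exactly N; this is asserted in the test suite and makes
SNR = P[N/3] / N.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sequence_io import Transcript

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: canonical names of the 89 features, fixed order
FEATURE_NAMES: list[str] = (
    ["MaxORF", "RMaxORF", "SNR", "Length", "(G+C)%"]
    + [f"{b}%" for b in BASES]
    + ["".join(p) + "%" for p in itertools.product(BASES, repeat=2)]
    + ["".join(p) + "%" for p in itertools.product(BASES, repeat=3)]
)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class IndicatorTracks:
    """Voss mapping: four binary indicator tracks, one per base.

    At every position exactly one track is 1, so the tracks partition the
    sequence.
    """

    u_A: np.ndarray
    u_C: np.ndarray
    u_G: np.ndarray
    u_T: np.ndarray

    @property
    def n(self) -> int:
        return len(self.u_A)

    def as_matrix(self) -> np.ndarray:
        """4 x N matrix in A, C, G, T row order."""
        return np.stack([self.u_A, self.u_C, self.u_G, self.u_T])


@dataclass
class PowerSpectrum:
    """Summed squared-magnitude DFT of the four indicator tracks."""

    P: np.ndarray
    n: int


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    enc = np.full(codes.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        enc[codes == ord(b)] = i
    if (enc < 0).any():
        pos = int(np.argmax(enc < 0))
        raise ValidationError(
            f"disallowed character {seq[pos]!r} at position {pos}"
        )
    return enc


def voss_mapping(seq: str) -> IndicatorTracks:
    """Encode a normalized {A,C,G,T} sequence as four binary tracks."""
    enc = _encode(seq)
    tracks = [(enc == i).astype(float) for i in range(4)]
    return IndicatorTracks(u_A=tracks[0], u_C=tracks[1], u_G=tracks[2], u_T=tracks[3])


def power_spectrum(tracks: IndicatorTracks) -> PowerSpectrum:
    """P[k] = sum over bases of |DFT(u_b)[k]|^2, k = 0..N-1."""
    mat = tracks.as_matrix()
    spectra = np.fft.fft(mat, axis=1)
    P = (spectra.real**2 + spectra.imag**2).sum(axis=0)
    return PowerSpectrum(P=P, n=tracks.n)


def snr(seq: str) -> float:
    """Period-3 signal-to-noise ratio P[k*]/mean(P).

    k* is the N/3 bin; for N not divisible by 3 the nearest bin round(N/3)
    is used (the fractional part is 1/3 or 2/3, so there is never a tie).
    """
    n = len(seq)
    if n < 3:
        raise ValidationError(f"sequence length {n} < 3; SNR undefined")
    ps = power_spectrum(voss_mapping(seq))
    k_star = int(round(n / 3))
    e_bar = ps.P.sum() / n
    return float(ps.P[k_star] / e_bar)


def max_orf(seq: str) -> int:
    """Longest ORF length in nt over the three forward frames.

    An ORF starts at ATG and runs to the first in-frame stop codon
    (TAA/TAG/TGA), stop included; an ATG with no downstream in-frame stop
    contributes nothing.  Returns 0 when no ORF exists, otherwise a multiple
    of 3 that is at least 6.
    """
    best = 0
    n = len(seq)
    for frame in range(3):
        first_atg = -1  # earliest open ATG since the last stop, this frame
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if first_atg >= 0:
                    best = max(best, i + 3 - first_atg)
                    first_atg = -1
            elif codon == "ATG" and first_atg < 0:
                first_atg = i
    return best


def rmax_orf(max_orf_nt: int, length: int) -> float:
    """Normalized longest-ORF length MaxORF / L, in [0, 1]."""
    if length <= 0:
        raise ValidationError("sequence length must be positive")
    if not 0 <= max_orf_nt <= length:
        raise ValidationError(
            f"max_orf {max_orf_nt} outside [0, {length}]"
        )
    return max_orf_nt / length


def kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies in lexicographic A<C<G<T order.

    Counts of the N-k+1 windows divided by N-k+1; the 4^k entries sum to 1.
    """
    if k not in (1, 2, 3):
        raise ValidationError(f"k must be 1, 2 or 3, got {k}")
    n = len(seq)
    if n < k:
        raise ValidationError(f"sequence length {n} < k = {k}")
    enc = _encode(seq)
    idx = enc[: n - k + 1].astype(np.int64).copy()
    for j in range(1, k):
        idx = idx * 4 + enc[j : n - k + 1 + j]
    counts = np.bincount(idx, minlength=4**k).astype(float)
    return counts / (n - k + 1)


def extract_features(t: Transcript | str) -> pd.Series:
    """Compute the full 89-entry feature vector for one cleaned transcript."""
    seq = t.seq if isinstance(t, Transcript) else t
    n = len(seq)
    orf = max_orf(seq)
    mono = kmer_frequencies(seq, 1)
    values = [
        float(orf),
        rmax_orf(orf, n),
        snr(seq),
        float(n),
        float(mono[_BASE_INDEX["G"]] + mono[_BASE_INDEX["C"]]),
    ]
    values.extend(mono)
    values.extend(kmer_frequencies(seq, 2))
    values.extend(kmer_frequencies(seq, 3))
    return pd.Series(values, index=FEATURE_NAMES, dtype=float)


def feature_frame(transcripts) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix (one row per transcript, id index) plus label series."""
    rows = [extract_features(t) for t in transcripts]
    ids = [t.id for t in transcripts]
    X = pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    y = pd.Series([t.label for t in transcripts], index=X.index, name="label")
    return X, y


def write_feature_table(X: pd.DataFrame, path) -> None:
    """Export the feature matrix as TSV with an id column."""
    X.to_csv(path, sep="\t", index=True, float_format="%.6g")
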