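"""Synthetic transcript generator for the two sequence classes.

Coding-like transcripts are built as 5' UTR + ATG + a run of sense codons
drawn from a strongly skewed codon-usage table + stop codon + 3' UTR, with
the ORF covering at least 60% of the sequence.  The codon bias skews the
nucleotide composition of the three codon positions, which is exactly the
mechanism that produces the period-3 spectral peak in real coding sequences —
no sinusoid is injected.  Non-coding-like transcripts are drawn from an
order-0 (or optionally order-1 Markov) base model with a target GC content
and no imposed ORF structure; incidental ORFs are deliberately not screened
out, which keeps the classification task non-trivial.

All emitted sequences fall inside the [200, 20000) training length window by
construction and use only {A,C,G,T}, so they survive cleaning untouched.
Generation is a pure function of the spec (fresh RNG per call), so the same
spec always yields byte-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .sequence_io import (
    CODING,
    NONCODING,
    Transcript,
    write_fasta,
    write_labels,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)

# heavily used codons (roughly the human-preferred set); the 8:1 weighting
# against the rest gives a strong codon-position composition bias
_PREFERRED = (
    "GCC", "CTG", "GAG", "AAG", "GAC", "TTC", "ATC", "AAC",
    "GGC", "CAG", "GTG", "TAC",
)


def default_codon_bias() -> np.ndarray:
    """Skewed probability table over the 61 sense codons (preferred 8:1)."""
    w = np.array([8.0 if c in _PREFERRED else 1.0 for c in SENSE_CODONS])
    return w / w.sum()


def _gc_base_probs(gc: float) -> np.ndarray:
    """Base probabilities over A,C,G,T hitting a target GC fraction."""
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    Lengths are drawn uniformly from ``length_range`` (default 200-3000 nt,
    inside the cleaning window).  ``codon_bias`` is a probability vector over
    the 61 sense codons in lexicographic order (default: the skewed table).
    ``noncoding_order`` selects an order-0 or order-1 Markov background with
    GC target ``noncoding_gc``; order-1 mixes a fraction ``markov_lag`` of
    self-transition into the base distribution, which leaves the stationary
    GC unchanged.
    """

    n_per_class: int = 1000
    length_range: tuple[int, int] = (200, 3000)
    codon_bias: np.ndarray = field(default_factory=default_codon_bias)
    utr_base_distribution: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    noncoding_order: int = 0
    noncoding_gc: float = 0.5
    markov_lag: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.codon_bias = np.asarray(self.codon_bias, dtype=float)
        self.utr_base_distribution = np.asarray(
            self.utr_base_distribution, dtype=float
        )
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        lo, hi = self.length_range
        if not (200 <= lo <= hi < 20000):
            raise ConfigurationError(
                f"length_range {self.length_range} must lie within [200, 20000)"
            )
        for name, p, size in (
            ("codon_bias", self.codon_bias, len(SENSE_CODONS)),
            ("utr_base_distribution", self.utr_base_distribution, 4),
        ):
            if p.shape != (size,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
                raise ConfigurationError(
                    f"{name} must be a length-{size} probability vector"
                )
        if self.noncoding_order not in (0, 1):
            raise ConfigurationError("noncoding_order must be 0 or 1")
        if not 0.0 < self.noncoding_gc < 1.0:
            raise ConfigurationError("noncoding_gc must lie in (0, 1)")


_BASES = np.array(list("ACGT"))


def _rng(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) % (2**31), stream])


def generate_coding(spec: GeneratorSpec) -> list[Transcript]:
    """Coding-like transcripts: UTR + biased-codon ORF (>= 60% of length) + UTR."""
    rng = _rng(spec, 0)
    lo, hi = spec.length_range
    codons = np.array(SENSE_CODONS)
    out: list[Transcript] = []
    for i in range(spec.n_per_class):
        n = int(rng.integers(lo, hi + 1))
        frac = rng.uniform(0.6, 0.85)
        n_codons = max(4, int(frac * n) // 3)  # includes ATG and stop
        orf_nt = 3 * n_codons
        max_utr5 = min(int(0.2 * n), n - orf_nt)
        utr5_len = int(rng.integers(0, max_utr5 + 1))
        utr3_len = n - orf_nt - utr5_len
        interior = rng.choice(codons, size=n_codons - 2, p=spec.codon_bias)
        stop = STOP_CODONS[int(rng.integers(0, 3))]
        utr5 = "".join(rng.choice(_BASES, size=utr5_len, p=spec.utr_base_distribution))
        utr3 = "".join(rng.choice(_BASES, size=utr3_len, p=spec.utr_base_distribution))
        seq = utr5 + "ATG" + "".join(interior) + stop + utr3
        out.append(Transcript(id=f"coding_{i:05d}", seq=seq, label=CODING))
    return out


def generate_noncoding(spec: GeneratorSpec) -> list[Transcript]:
    """Non-coding-like transcripts from the GC-matched Markov background."""
    rng = _rng(spec, 1)
    lo, hi = spec.length_range
    p = _gc_base_probs(spec.noncoding_gc)
    out: list[Transcript] = []
    for i in range(spec.n_per_class):
        n = int(rng.integers(lo, hi + 1))
        if spec.noncoding_order == 0:
            idx = rng.choice(4, size=n, p=p)
        else:
            lag = spec.markov_lag
            idx = np.empty(n, dtype=int)
            idx[0] = rng.choice(4, p=p)
            for j in range(1, n):
                if rng.random() < lag:
                    idx[j] = idx[j - 1]
                else:
                    idx[j] = rng.choice(4, p=p)
        seq = "".join(_BASES[idx])
        out.append(Transcript(id=f"noncoding_{i:05d}", seq=seq, label=NONCODING))
    return out


def generate_dataset(spec: GeneratorSpec) -> list[Transcript]:
    """Both classes, coding first, in generation order."""
    return generate_coding(spec) + generate_noncoding(spec)


def make_dataset(spec: GeneratorSpec, out_dir) -> dict[str, Path]:
    """Write coding.fasta, noncoding.fasta and labels.tsv to out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coding = generate_coding(spec)
    noncoding = generate_noncoding(spec)
    paths = {
        "coding": out_dir / "coding.fasta",
        "noncoding": out_dir / "noncoding.fasta",
        "labels": out_dir / "labels.tsv",
    }
    write_fasta(coding, paths["coding"])
    write_fasta(noncoding, paths["noncoding"])
    write_labels(coding + noncoding, paths["labels"])
    return paths


def with_seed(spec: GeneratorSpec, seed: int) -> GeneratorSpec:
    """Copy of the spec with a different seed (conditions unchanged)."""
    return replace(spec, seed=seed)
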