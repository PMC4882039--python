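"""Reading, cleaning and reporting of transcript sequences.

Transcripts are plain nucleotide strings with a FASTA-style identifier and an
optional class label (CODING / NONCODING / UNKNOWN).  Cleaning normalizes the
alphabet to uppercase {A,C,G,T} (U -> T), rejects records containing any other
character, applies the half-open length window [min_len, max_len) used to
build training sets of transcripts longer than 200 nt and shorter than
20 kb, and optionally removes exact duplicate sequences.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ConfigurationError, ValidationError

CODING = "CODING"
NONCODING = "NONCODING"
UNKNOWN = "UNKNOWN"

_ALLOWED_RAW = set("AaCcGgTtUu")

# normalization table: uppercase and U->T
_NORMALIZE = str.maketrans("acgtuU", "ACGTTT")


@dataclass
class Transcript:
    """One nucleotide sequence with id and optional class label."""

    id: str
    seq: str
    label: str = UNKNOWN
    flagged_length: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CleaningReport:
    """Bookkeeping for one cleaning pass; counts reconcile with input size."""

    kept: int = 0
    rejected_alphabet: int = 0
    rejected_length: int = 0
    rejected_duplicate: int = 0
    flagged_length: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return (
            self.kept
            + self.rejected_alphabet
            + self.rejected_length
            + self.rejected_duplicate
        )


def read_fasta(path: str | Path) -> list[Transcript]:
    """Parse a FASTA file into Transcripts (label UNKNOWN, case preserved).

    The id is the first whitespace-delimited token of the header; sequence
    lines are concatenated.  A record with an empty sequence raises
    ValidationError naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: list[Transcript] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValidationError(f"record {rec.id!r} has an empty sequence")
        out.append(Transcript(id=rec.id, seq=seq))
    return out


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U->T; raise if any disallowed character is present."""
    bad = set(seq) - _ALLOWED_RAW
    if bad:
        raise ValidationError(
            f"disallowed characters {sorted(bad)} in sequence"
        )
    return seq.translate(_NORMALIZE)


def clean_transcripts(
    records: Iterable[Transcript],
    min_len: int = 200,
    max_len: int = 20000,
    drop_duplicates: bool = True,
    length_action: str = "reject",
) -> tuple[list[Transcript], CleaningReport]:
    """Normalize and filter transcripts.

    Records with characters outside {A,a,C,c,G,g,T,t,U,u} are rejected whole.
    Length is checked post-normalization against the half-open window
    [min_len, max_len); with ``length_action="flag"`` (predict mode) the
    out-of-range records are kept but marked instead of dropped.  Exact
    duplicate sequences beyond the first are rejected when
    ``drop_duplicates`` is set.
    """
    if min_len > max_len:
        raise ConfigurationError(
            f"min_len ({min_len}) exceeds max_len ({max_len})"
        )
    if length_action not in ("reject", "flag"):
        raise ConfigurationError(f"unknown length_action {length_action!r}")
    report = CleaningReport()
    seen: set[str] = set()
    kept: list[Transcript] = []
    for rec in records:
        try:
            norm = normalize_sequence(rec.seq)
        except ValidationError:
            report.rejected_alphabet += 1
            report.rejections.append((rec.id, "alphabet"))
            continue
        in_range = min_len <= len(norm) < max_len
        if not in_range and length_action == "reject":
            report.rejected_length += 1
            report.rejections.append((rec.id, "length"))
            continue
        if drop_duplicates:
            if norm in seen:
                report.rejected_duplicate += 1
                report.rejections.append((rec.id, "duplicate"))
                continue
            seen.add(norm)
        flagged = not in_range
        if flagged:
            report.flagged_length += 1
        kept.append(
            Transcript(id=rec.id, seq=norm, label=rec.label, flagged_length=flagged)
        )
        report.kept += 1
    return kept, report


def write_fasta(records: Sequence[Transcript], path: str | Path, width: int = 70) -> None:
    """Write transcripts as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_labels(records: Sequence[Transcript], path: str | Path) -> None:
    """Write a two-column id/label TSV for a set of transcripts."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "label"])
        for rec in records:
            w.writerow([rec.id, rec.label])


def read_labels(path: str | Path) -> dict[str, str]:
    """Read an id/label TSV produced by :func:`write_labels`."""
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValidationError(f"label table {path} lacks an 'id' column")
        for row in reader:
            labels[row["id"]] = row["label"]
    return labels


def _fmt(x: float) -> str:
    if isinstance(x, bool):
        return str(x).lower()
    if isinstance(x, int):
        return str(x)
    return f"{x:.6g}"


def write_report(predictions: Sequence, path: str | Path) -> None:
    """Write the per-transcript prediction report as TSV.

    Columns: id, noncoding_score, predicted_class, shortcut_applied, then one
    column per selected feature value.  Rows preserve input order.
    """
    feature_names: list[str] = []
    if predictions:
        feature_names = list(predictions[0].features.keys())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "noncoding_score", "predicted_class", "shortcut_applied"]
                   + feature_names)
        for p in predictions:
            w.writerow(
                [p.id, _fmt(p.noncoding_score), p.predicted,
                 _fmt(p.shortcut_applied)]
                + [_fmt(p.features[name]) for name in feature_names]
            )


def write_rejection_log(report: CleaningReport, path: str | Path) -> None:
    """Write the rejected-record log (id, reason code) alongside a run."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "reason"])
        for rec_id, reason in report.rejections:
            w.writerow([rec_id, reason])
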