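"""FASTQ parsing and sequence cleaning.

Amplicon classifiers in this package consume only the raw base strings of
each read; identifiers and quality lines carry no signal for k-mer
featurization and are stripped immediately after parsing.  The parser is
deliberately strict: records must be exactly four lines (no line-wrapped
FASTQ), because downstream window counting assumes one read per record.

Only ``N`` is tolerated as a non-ACGT base — it is the one ambiguity code
that routinely appears in amplicon data; rarer IUPAC codes are rejected so
that every retained character has a defined place in the 4-letter De Bruijn
alphabet (N-containing windows are later skipped, not imputed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "FastqRecord",
    "CleanSample",
    "FastqParseError",
    "SequenceValidationError",
    "LabelError",
    "read_fastq",
    "clean_sample",
    "filter_low_read_samples",
    "load_labels",
    "write_reads",
    "read_reads",
    "load_sample_dir",
]

VALID_BASES = frozenset("ACGTN")

#: Diagnosis strings mapped to the diseased class (forms of IBD).
DISEASED_DIAGNOSES = frozenset({"CD", "UC", "IC", "IBD"})
#: Diagnosis strings mapped to the healthy class.
HEALTHY_DIAGNOSES = frozenset({"NO", "NONIBD", "NON-IBD", "NO-IBD", "CONTROL", "HEALTHY", "HC"})


class FastqParseError(ValueError):
    """Malformed FASTQ block (bad sentinel or quality/sequence mismatch)."""


class SequenceValidationError(ValueError):
    """A read contains characters outside {A,C,G,T,N}."""


class LabelError(ValueError):
    """Label table contains unknown diagnoses or duplicate sample ids."""


@dataclass
class FastqRecord:
    """One four-line FASTQ record, kept verbatim."""

    identifier: str
    sequence: str
    plus_line: str
    quality: str


@dataclass
class CleanSample:
    """A sample reduced to its raw reads (uppercase, {A,C,G,T,N} only)."""

    sample_id: str
    reads: list[str] = field(default_factory=list)
    label: Optional[int] = None

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def read_fastq(path: str | Path) -> list[FastqRecord]:
    """Parse a strict 4-line-record FASTQ file.

    Raises
    ------
    FastqParseError
        If the line count is not a multiple of four, a sentinel character
        is wrong, or quality and sequence lengths differ.  The message
        names the 1-based record index.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    # trailing blank line from a final newline is not part of a record
    if lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise FastqParseError(
            f"{path}: line count {len(lines)} is not a multiple of 4"
        )
    records: list[FastqRecord] = []
    for i in range(0, len(lines), 4):
        idx = i // 4 + 1
        ident, seq, plus, qual = lines[i : i + 4]
        if not ident.startswith("@"):
            raise FastqParseError(
                f"{path}: record {idx}: identifier line does not start with '@'"
            )
        if not plus.startswith("+"):
            raise FastqParseError(
                f"{path}: record {idx}: separator line does not start with '+'"
            )
        if len(qual) != len(seq):
            raise FastqParseError(
                f"{path}: record {idx}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        records.append(FastqRecord(ident, seq, plus, qual))
    return records


def clean_sample(records: Sequence[FastqRecord], sample_id: str) -> CleanSample:
    """Strip records down to uppercase base strings, preserving order.

    Raises
    ------
    SequenceValidationError
        If any read contains a character outside {A,C,G,T,N} (case
        insensitive); the message names the 1-based read index.
    """
    reads: list[str] = []
    for i, rec in enumerate(records, start=1):
        seq = rec.sequence.upper()
        if not set(seq) <= VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            raise SequenceValidationError(
                f"sample {sample_id!r}: read {i} contains invalid characters {bad}"
            )
        reads.append(seq)
    return CleanSample(sample_id=sample_id, reads=reads)


def filter_low_read_samples(
    samples: Iterable[CleanSample], min_reads: int
) -> tuple[list[CleanSample], list[str]]:
    """Partition samples into (kept, excluded ids) by a read-count floor.

    Public 16S cohorts occasionally contain near-empty sequence files;
    those are dropped before featurization.  ``min_reads`` is a parameter
    because no universal threshold exists.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    kept: list[CleanSample] = []
    excluded: list[str] = []
    for sample in samples:
        if sample.n_reads >= min_reads:
            kept.append(sample)
        else:
            excluded.append(sample.sample_id)
    return kept, excluded


def load_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column (sample_id, diagnosis) CSV into binary labels.

    The forms of inflammatory bowel disease (CD, UC, IC) map to 1;
    control/no-IBD strings map to 0.  Bare ``0``/``1`` are also accepted.
    """
    path = Path(path)
    labels: dict[str, int] = {}
    bad_rows: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise LabelError(f"{path}: empty label file")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                bad_rows.append(f"line {lineno}: {row!r}")
                continue
            sample_id = row[0].strip()
            diagnosis = row[1].strip().upper()
            if sample_id in labels:
                raise LabelError(f"{path}: duplicate sample_id {sample_id!r}")
            if diagnosis in DISEASED_DIAGNOSES or diagnosis == "1":
                labels[sample_id] = 1
            elif diagnosis in HEALTHY_DIAGNOSES or diagnosis == "0":
                labels[sample_id] = 0
            else:
                bad_rows.append(f"line {lineno}: unknown diagnosis {row[1]!r}")
    if bad_rows:
        raise LabelError(f"{path}: malformed rows:\n  " + "\n  ".join(bad_rows))
    return labels


def write_reads(sample: CleanSample, path: str | Path) -> None:
    """Write the plain-sequence intermediate: one read per line."""
    Path(path).write_text("".join(r + "\n" for r in sample.reads))


def read_reads(path: str | Path, sample_id: str | None = None) -> CleanSample:
    """Read the plain-sequence intermediate back into a CleanSample."""
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    reads = [line for line in path.read_text().splitlines() if line]
    sample = CleanSample(sample_id=sample_id, reads=[])
    for i, read in enumerate(reads, start=1):
        seq = read.upper()
        if not set(seq) <= VALID_BASES:
            raise SequenceValidationError(
                f"sample {sample_id!r}: read {i} contains invalid characters"
            )
        sample.reads.append(seq)
    return sample


def load_sample_dir(
    fastq_dir: str | Path,
    labels_path: str | Path | None = None,
    min_reads: int = 10,
) -> tuple[list[CleanSample], list[str]]:
    """Load every ``*.fastq``/``*.fq`` in a directory as a CleanSample.

    Sample ids are file stems; labels, if given, are attached from the
    label table.  Returns (kept samples, excluded sample ids).
    """
    fastq_dir = Path(fastq_dir)
    paths = sorted(
        p for p in fastq_dir.iterdir() if p.suffix in {".fastq", ".fq"}
    )
    if not paths:
        raise FileNotFoundError(f"no FASTQ files in {fastq_dir}")
    labels = load_labels(labels_path) if labels_path is not None else {}
    samples = []
    for p in paths:
        sample = clean_sample(read_fastq(p), sample_id=p.stem)
        if sample.sample_id in labels:
            sample.label = labels[sample.sample_id]
        samples.append(sample)
    return filter_low_read_samples(samples, min_reads)
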