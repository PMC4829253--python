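"""Multi-FASTA input/output and sequence utilities.

Coordinates everywhere in this package are 0-based, half-open.  FASTA
parsing and complement tables are delegated to Biopython; this module adds
the validation layer (duplicate ids, empty records, non-IUPAC characters
are collected into a report without aborting) and a streaming iterator so
million-record EST sets never need to fit in memory at once.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq

from .enzyme_db import IUPAC_SETS

__all__ = [
    "SequenceRecord",
    "ValidationReport",
    "read_fasta",
    "iter_fasta",
    "write_fasta",
    "write_tsv",
    "reverse_complement",
    "chunked",
]

_PathLike = Union[str, Path]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record, uppercase, with orientation bookkeeping."""

    id: str
    seq: str
    origin_orientation: str = "as-input"  # or "reverse-complemented"

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        flipped = ("reverse-complemented"
                   if self.origin_orientation == "as-input" else "as-input")
        return SequenceRecord(self.id, reverse_complement(self.seq), flipped)


@dataclass
class ValidationReport:
    """Irregularities found while reading a FASTA file."""

    warnings: list[str] = field(default_factory=list)
    n_read: int = 0
    n_kept: int = 0

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)

    @property
    def ok(self) -> bool:
        return not self.warnings


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (involution)."""
    return str(Seq(seq).reverse_complement())


def _open_text(path: _PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8", newline=None)


def iter_fasta(path: _PathLike) -> Iterator[SequenceRecord]:
    """Stream records from a (possibly gzipped) FASTA file, uppercased."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield SequenceRecord(id=rec.id, seq=str(rec.seq).upper())


def validate_records(
    records: Iterable[SequenceRecord], strict: bool = False
) -> tuple[list[SequenceRecord], ValidationReport]:
    """Validate records: empty sequences and duplicate ids are dropped with
    a warning; non-IUPAC characters warn and, under ``strict``, drop."""
    report = ValidationReport()
    seen: set[str] = set()
    kept: list[SequenceRecord] = []
    for rec in records:
        report.n_read += 1
        if not rec.seq:
            report.warn(f"{rec.id}: empty sequence, dropped")
            continue
        if rec.id in seen:
            report.warn(f"{rec.id}: duplicate id, dropped")
            continue
        bad = sorted({c for c in rec.seq if c not in IUPAC_SETS})
        if bad:
            if strict:
                report.warn(f"{rec.id}: non-IUPAC characters {bad}, dropped (strict)")
                continue
            report.warn(f"{rec.id}: non-IUPAC characters {bad}, kept")
        seen.add(rec.id)
        kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def read_fasta(
    path: _PathLike, strict: bool = False
) -> tuple[list[SequenceRecord], ValidationReport]:
    """Read and validate a multi-FASTA file.

    Raises ``ValueError`` if no valid records remain; irregularities short
    of that are collected into the report without aborting.
    """
    records, report = validate_records(iter_fasta(path), strict=strict)
    if not records:
        raise ValueError(f"{path}: no valid FASTA records")
    return records, report


def write_fasta(records: Iterable[SequenceRecord], path: _PathLike) -> None:
    """Write records as 60-column-wrapped FASTA (read∘write is identity
    on id and sequence)."""
    with open(path, "w", encoding="utf-8") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                out.write(rec.seq[i : i + 60] + "\n")


def write_tsv(table, path: _PathLike) -> None:
    """Write a pandas DataFrame as a TSV (header always present)."""
    table.to_csv(path, sep="\t", index=False)


def chunked(records: Iterable[SequenceRecord], size: int) -> Iterator[list[SequenceRecord]]:
    """Yield successive chunks of at most ``size`` records (collation-style
    processing for datasets too large for one pass in memory)."""
    if size < 1:
        raise ValueError("chunk size must be >= 1")
    chunk: list[SequenceRecord] = []
    for rec in records:
        chunk.append(rec)
        if len(chunk) == size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk
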