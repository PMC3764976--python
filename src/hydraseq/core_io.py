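"""Sequence record model and FASTA/FASTQ/QUAL readers and writers.

All pipeline stages exchange :class:`SeqRecord` (nucleotide, optional Phred
qualities) and :class:`ProteinRecord` objects.  Records are immutable; stages
return new records rather than mutating inputs.

The readers carry a deliberately strict error contract: malformed input raises
:class:`FormatError` naming the offending line, and duplicate identifiers
within one file are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed sequence files; message names the line number."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A nucleotide sequence with optional per-base Phred qualities.

    ``seq`` is uppercased on construction.  When ``qual`` is present it must
    have one integer per base.
    """

    id: str
    seq: str
    description: str = ""
    qual: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        if self.qual is not None:
            object.__setattr__(self, "qual", tuple(int(q) for q in self.qual))
            if len(self.qual) != len(self.seq):
                raise ValueError(
                    f"record {self.id!r}: qual length {len(self.qual)} "
                    f"!= seq length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> "SeqRecord":
        """Return a new record holding seq[start:end] (and matching qual)."""
        qual = self.qual[start:end] if self.qual is not None else None
        return replace(self, seq=self.seq[start:end], qual=qual)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence deduced from a transcript."""

    id: str
    seq: str
    source_transcript: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


def _check_unique_ids(records: Sequence, path) -> None:
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FormatError(f"{path}: duplicate record id(s): {', '.join(dups)}")


def _header_id(line: str) -> tuple[str, str]:
    """Split a '>' / '@' header body into (id, description)."""
    parts = line.split(None, 1)
    ident = parts[0] if parts else ""
    desc = parts[1].strip() if len(parts) > 1 else ""
    return ident, desc


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into records, in file order.

    Multi-line sequences are joined and uppercased.  Raises
    :class:`FormatError` for an empty file, a malformed or empty header, or
    duplicate ids.
    """
    records: list[SeqRecord] = []
    ident: str | None = None
    desc = ""
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if ident is not None:
                    records.append(SeqRecord(ident, "".join(chunks), desc))
                ident, desc = _header_id(line[1:])
                if not ident:
                    raise FormatError(f"{path}: line {lineno}: empty FASTA header")
                chunks = []
            else:
                if ident is None:
                    raise FormatError(
                        f"{path}: line {lineno}: sequence data before first header"
                    )
                chunks.append(line)
    if ident is not None:
        records.append(SeqRecord(ident, "".join(chunks), desc))
    if not records:
        raise FormatError(f"{path}: line 1: empty FASTA file")
    _check_unique_ids(records, path)
    return records


def write_fasta(records: Iterable[SeqRecord | ProteinRecord], path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_qual(path) -> dict[str, tuple[int, ...]]:
    """Read a QUAL file (FASTA-style headers, whitespace-separated ints)."""
    quals: dict[str, tuple[int, ...]] = {}
    ident: str | None = None
    vals: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if ident is not None:
                    quals[ident] = tuple(vals)
                ident, _ = _header_id(line[1:])
                if not ident:
                    raise FormatError(f"{path}: line {lineno}: empty QUAL header")
                if ident in quals:
                    raise FormatError(f"{path}: line {lineno}: duplicate id {ident!r}")
                vals = []
            else:
                if ident is None:
                    raise FormatError(
                        f"{path}: line {lineno}: quality data before first header"
                    )
                try:
                    vals.extend(int(tok) for tok in line.split())
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-integer quality value"
                    ) from None
    if ident is not None:
        quals[ident] = tuple(vals)
    if not quals:
        raise FormatError(f"{path}: line 1: empty QUAL file")
    return quals


def read_fasta_qual(fasta_path, qual_path) -> list[SeqRecord]:
    """Read paired FASTA + QUAL files into quality-bearing records."""
    records = read_fasta(fasta_path)
    quals = read_qual(qual_path)
    out = []
    for rec in records:
        if rec.id not in quals:
            raise FormatError(f"{qual_path}: no quality entry for record {rec.id!r}")
        out.append(replace(rec, qual=quals[rec.id]))
    return out


def write_fasta_qual(records: Sequence[SeqRecord], fasta_path, qual_path) -> None:
    """Write paired FASTA and QUAL files, same record order and ids.

    Every record must carry qualities; round-trips through
    :func:`read_fasta_qual`.
    """
    for rec in records:
        if rec.qual is None:
            raise ValueError(f"record {rec.id!r} has no quality values")
    write_fasta(records, fasta_path)
    with open(qual_path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            fh.write(" ".join(str(q) for q in rec.qual) + "\n")


def read_fastq(path, phred_offset: int = 33) -> list[SeqRecord]:
    """Read 4-line FASTQ; qualities decoded with ``phred_offset`` (33 or 64)."""
    records: list[SeqRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: line 1: empty FASTQ file")
    if len(lines) % 4 != 0:
        raise FormatError(
            f"{path}: line {len(lines)}: truncated FASTQ record "
            f"(file has {len(lines)} lines, not a multiple of 4)"
        )
    for i in range(0, len(lines), 4):
        head, seq, plus, qline = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FormatError(f"{path}: line {lineno}: FASTQ header must start with '@'")
        ident, desc = _header_id(head[1:])
        if not ident:
            raise FormatError(f"{path}: line {lineno}: empty FASTQ header")
        if not plus.startswith("+"):
            raise FormatError(f"{path}: line {lineno + 2}: separator line must start with '+'")
        if len(qline) != len(seq):
            raise FormatError(
                f"{path}: line {lineno + 3}: quality length {len(qline)} "
                f"!= sequence length {len(seq)}"
            )
        qual = tuple(ord(c) - phred_offset for c in qline)
        if any(q < 0 for q in qual):
            raise FormatError(
                f"{path}: line {lineno + 3}: quality character below Phred+{phred_offset} range"
            )
        records.append(SeqRecord(ident, seq, desc, qual))
    _check_unique_ids(records, path)
    return records


def write_fastq(records: Sequence[SeqRecord], path, phred_offset: int = 33) -> None:
    """Write 4-line FASTQ; every record must carry qualities."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no quality values")
            header = f"@{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n" + rec.seq + "\n+\n")
            fh.write("".join(chr(q + phred_offset) for q in rec.qual) + "\n")
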