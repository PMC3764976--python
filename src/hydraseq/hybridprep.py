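"""Preparation of short-read contigs for hybrid co-assembly with 454 reads.

To bias a 454-era overlap assembler towards the (more accurate) short-read
contigs, each contig is (1) duplicated with the first base removed from the
duplicate so the pair is not an exact repeat, (2) chopped into 1999-nt
segments overlapping by 1899 nt whenever it exceeds the assembler's input
length cap, and (3) given an artificial quality string: Phred 40 for internal
bases, Phred 10 over the 25-bp edges, which are more error prone.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import SeqRecord


@dataclass
class ChopParams:
    max_len: int = 1999
    overlap: int = 1899
    edge_qual: int = 10
    internal_qual: int = 40
    edge_len: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.overlap < self.max_len:
            raise ValueError("require 0 < overlap < max_len")

    @property
    def step(self) -> int:
        return self.max_len - self.overlap


def duplicate_contigs(contigs: list[SeqRecord]) -> list[SeqRecord]:
    """Original + one duplicate per contig; duplicate drops the first base
    and takes the suffix ``_dup`` on its id."""
    out: list[SeqRecord] = []
    for rec in contigs:
        out.append(rec)
        out.append(SeqRecord(rec.id + "_dup", rec.seq[1:], rec.description))
    return out


def chop_starts(length: int, params: ChopParams) -> list[int]:
    """Segment start positions tiling ``length`` with fixed-size windows.

    Regular starts advance by ``step``; if they leave an uncovered tail, a
    final clamped segment starting at ``length - max_len`` is appended so
    every base is covered and all segments have exactly ``max_len`` bases.
    """
    if length <= params.max_len:
        return [0]
    last = length - params.max_len
    starts = list(range(0, last + 1, params.step))
    if starts[-1] != last:
        starts.append(last)
    return starts


def chop_contig(rec: SeqRecord, params: ChopParams | None = None) -> list[SeqRecord]:
    """Split a contig into overlapping max_len segments (identity if short)."""
    params = params or ChopParams()
    if len(rec.seq) <= params.max_len:
        return [rec]
    return [
        SeqRecord(f"{rec.id}_part{k}", rec.seq[s : s + params.max_len], rec.description)
        for k, s in enumerate(chop_starts(len(rec.seq), params))
    ]


def synthesize_quality(length: int, params: ChopParams | None = None) -> tuple[int, ...]:
    """Artificial Phred values: weak edges, strong interior."""
    params = params or ChopParams()
    if length < 1:
        raise ValueError("length must be >= 1")
    qual = [params.internal_qual] * length
    e = min(params.edge_len, length)
    for i in range(e):
        qual[i] = params.edge_qual
        qual[length - 1 - i] = params.edge_qual
    return tuple(qual)


def prepare_hybrid_input(
    contigs: list[SeqRecord], params: ChopParams | None = None
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Duplicate, chop and attach artificial qualities, in that order.

    Returns assembler-ready records (with qual) and a manifest mapping each
    output segment to its source contig, duplicate status and segment start.
    """
    params = params or ChopParams()
    records: list[SeqRecord] = []
    rows = []
    for rec in duplicate_contigs(contigs):
        is_dup = rec.id.endswith("_dup")
        source = rec.id[:-4] if is_dup else rec.id
        if len(rec.seq) <= params.max_len:
            starts = [0]
            segments = [rec]
        else:
            starts = chop_starts(len(rec.seq), params)
            segments = chop_contig(rec, params)
        for seg, start in zip(segments, starts):
            records.append(
                SeqRecord(seg.id, seg.seq, seg.description, synthesize_quality(len(seg.seq), params))
            )
            rows.append(
                dict(segment_id=seg.id, source_id=source, is_duplicate=is_dup,
                     segment_start=start, length=len(seg.seq))
            )
    manifest = pd.DataFrame(rows, columns=["segment_id", "source_id", "is_duplicate",
                                           "segment_start", "length"])
    return records, manifest


#: Assembler parameters recorded for provenance in manifest headers only; the
#: assemblies themselves are performed by external tools.
ASSEMBLER_PROVENANCE = "minimum_overlap=50bp minimum_identity=95%"


def write_manifest(manifest: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# hybrid assembly input manifest ({ASSEMBLER_PROVENANCE})\n")
        manifest.to_csv(fh, sep="\t", index=False)
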