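"""Read and contig cleaning heuristics for Illumina and 454-style data.

The Illumina cleaner runs a fixed pipeline on each 76-nt barcoded read:
barcode stripping, exact adapter-prefix truncation, inexact 3'-anchored
adapter-overlap trimming, 3'-terminal homopolymer removal, then the
low-quality-fraction and minimum-length discards.  The quality and length
discards are judged on the final trimmed read.

Contig edges carrying trans-spliced-leader hallmarks (TAAG within the first
15 bp, or its reverse complement CTTA within the last 15 bp) are cut off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_io import SeqRecord

DISCARD_LOW_QUALITY = "low_quality"
DISCARD_TOO_SHORT = "too_short"


@dataclass
class CleanParams:
    """Constants of the cleaning heuristics (defaults as used throughout)."""

    barcode_len: int = 5
    adapter_seqs: tuple[str, ...] = ()
    adapter_prefix_len: int = 12
    adapter_min_overlap: int = 8
    adapter_max_mismatch: int = 1
    homopolymer_max: int = 5
    lowq_phred: int = 5
    lowq_frac: float = 0.90
    min_len: int = 30
    edge_window: int = 15
    leader_motif: str = "TAAG"
    leader_motif_rc: str = "CTTA"

    def __post_init__(self) -> None:
        if not 0 < self.lowq_frac <= 1:
            raise ValueError("lowq_frac must be in (0, 1]")
        for name in ("barcode_len", "adapter_prefix_len", "homopolymer_max",
                     "min_len", "edge_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.adapter_seqs = tuple(a.upper() for a in self.adapter_seqs)


@dataclass
class CleanReport:
    """Per-filter accounting for a cleaned dataset."""

    n_input: int = 0
    n_output: int = 0
    counts: dict = field(default_factory=dict)

    @property
    def retention_pct(self) -> int:
        return retention_percent(self.n_input, self.n_output)

    def bump(self, key: str) -> None:
        self.counts[key] = self.counts.get(key, 0) + 1


def retention_percent(n_raw: int, n_kept: int) -> int:
    """Integer percentage of reads surviving cleaning (report arithmetic)."""
    if n_raw <= 0:
        raise ValueError("raw count must be positive")
    return round(100.0 * n_kept / n_raw)


def _trim_adapter_exact(rec: SeqRecord, params: CleanParams) -> tuple[SeqRecord, bool]:
    """Truncate at the first exact occurrence of any adapter's 12-bp prefix."""
    cut = None
    for adapter in params.adapter_seqs:
        prefix = adapter[: params.adapter_prefix_len]
        pos = rec.seq.find(prefix)
        if pos != -1 and (cut is None or pos < cut):
            cut = pos
    if cut is None:
        return rec, False
    return rec.slice(0, cut), True


def _trim_adapter_overlap(rec: SeqRecord, params: CleanParams) -> tuple[SeqRecord, bool]:
    """Trim a 3'-anchored partial adapter: suffix of the read matching an
    adapter prefix over >= adapter_min_overlap nt with <= adapter_max_mismatch
    mismatches.  The longest qualifying overlap is removed."""
    seq = rec.seq
    for adapter in params.adapter_seqs:
        max_l = min(len(seq), len(adapter))
        for length in range(max_l, params.adapter_min_overlap - 1, -1):
            tail = seq[-length:]
            mism = sum(1 for a, b in zip(tail, adapter[:length]) if a != b)
            if mism <= params.adapter_max_mismatch:
                return rec.slice(0, len(seq) - length), True
    return rec, False


def _trim_homopolymer(rec: SeqRecord, params: CleanParams) -> tuple[SeqRecord, bool]:
    """Remove a 3'-terminal homopolymer run longer than ``homopolymer_max``
    (the entire run is removed, not trimmed back to the maximum)."""
    seq = rec.seq
    if not seq:
        return rec, False
    run = 1
    while run < len(seq) and seq[-run - 1] == seq[-1]:
        run += 1
    if run > params.homopolymer_max:
        return rec.slice(0, len(seq) - run), True
    return rec, False


def clean_illumina_read(rec: SeqRecord, params: CleanParams,
                        _report: CleanReport | None = None) -> SeqRecord | None:
    """Clean one Illumina read; returns the cleaned record or None if discarded."""
    if rec.qual is None:
        raise ValueError(f"read {rec.id!r} has no quality values")
    out = rec.slice(params.barcode_len, len(rec))
    out, hit = _trim_adapter_exact(out, params)
    if hit and _report:
        _report.bump("adapter_exact")
    if out.seq:
        out, hit = _trim_adapter_overlap(out, params)
        if hit and _report:
            _report.bump("adapter_overlap")
    if out.seq:
        out, hit = _trim_homopolymer(out, params)
        if hit and _report:
            _report.bump("homopolymer")
    n = len(out.seq)
    if n and sum(1 for q in out.qual if q <= params.lowq_phred) > params.lowq_frac * n:
        if _report:
            _report.bump(DISCARD_LOW_QUALITY)
        return None
    if n < params.min_len:
        if _report:
            _report.bump(DISCARD_TOO_SHORT)
        return None
    return out


def clean_contig_edges(rec: SeqRecord, params: CleanParams | None = None) -> SeqRecord:
    """Cut trans-spliced-leader hallmarks off contig edges.

    If TAAG occurs entirely within the first ``edge_window`` bp, the prefix
    through the end of the *last* such occurrence is removed (maximal leader
    removal); symmetrically, if CTTA occurs entirely within the last
    ``edge_window`` bp, the suffix from the *first* such occurrence is
    removed.  Applied once, 5' side then 3' side.
    """
    params = params or CleanParams()
    seq = rec.seq
    motif, motif_rc = params.leader_motif, params.leader_motif_rc
    w = params.edge_window
    # 5' side: last occurrence fully inside the first w bases
    cut5 = 0
    start = 0
    while True:
        pos = seq.find(motif, start)
        if pos == -1 or pos + len(motif) > w:
            break
        cut5 = pos + len(motif)
        start = pos + 1
    if cut5:
        seq = seq[cut5:]
    # 3' side: first occurrence fully inside the last w bases
    cut3 = None
    lo = max(0, len(seq) - w)
    pos = seq.find(motif_rc, lo)
    if pos != -1:
        cut3 = pos
    if cut3 is not None:
        seq = seq[:cut3]
    if cut5 or cut3 is not None:
        qual = rec.qual[cut5 : cut5 + len(seq)] if rec.qual is not None else None
        return SeqRecord(rec.id, seq, rec.description, qual)
    return rec


def clean_454_read(rec: SeqRecord, adapters: Sequence[str] = (),
                   leaders: Sequence[str] = (),
                   params: CleanParams | None = None,
                   _report: CleanReport | None = None) -> SeqRecord | None:
    """Trim exact adapter/leader occurrences anchored within ``edge_window``
    bp of either read end (the intervening edge is removed too), then apply
    the minimum-length filter."""
    params = params or CleanParams()
    probes = [p.upper() for p in (*adapters, *leaders) if p]
    out = rec
    changed = True
    while changed:  # repeated leaders at an edge are peeled one by one
        changed = False
        seq = out.seq
        for probe in probes:
            pos = seq.find(probe)
            if pos != -1 and pos < params.edge_window:
                out = out.slice(pos + len(probe), len(seq))
                changed = True
                break
            pos = seq.rfind(probe)
            if pos != -1 and pos + len(probe) > len(seq) - params.edge_window:
                out = out.slice(0, pos)
                changed = True
                break
    if _report and len(out.seq) != len(rec.seq):
        _report.bump("edge_trim")
    if len(out.seq) < params.min_len:
        if _report:
            _report.bump(DISCARD_TOO_SHORT)
        return None
    return out


def clean_dataset(records: Iterable[SeqRecord], params: CleanParams,
                  kind: str = "illumina",
                  adapters: Sequence[str] = (),
                  leaders: Sequence[str] = ()) -> tuple[list[SeqRecord], CleanReport]:
    """Clean a homogeneous dataset with the appropriate per-read cleaner.

    ``kind`` is one of ``illumina``, ``454`` or ``contigs``.
    """
    report = CleanReport()
    out: list[SeqRecord] = []
    for rec in records:
        report.n_input += 1
        if kind == "illumina":
            cleaned = clean_illumina_read(rec, params, _report=report)
        elif kind == "454":
            cleaned = clean_454_read(rec, adapters, leaders, params, _report=report)
        elif kind == "contigs":
            cleaned = clean_contig_edges(rec, params)
        else:
            raise ValueError(f"unknown dataset kind {kind!r}")
        if cleaned is not None:
            out.append(cleaned)
            report.n_output += 1
    return out, report
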