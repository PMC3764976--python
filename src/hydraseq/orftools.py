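"""Six-frame translation, longest-ORF extraction and ORF-coverage profiling.

An ORF here is a stop-codon-free stretch of codons in one of the six reading
frames (stop-to-stop or end-bounded); a leading ATG is *not* required.  A
"full-length" ORF additionally starts with ATG and ends at a stop codon.
The stop codon is excluded from the peptide but included in the nucleotide
span when present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .core_io import ProteinRecord, SeqRecord, revcomp


@dataclass(frozen=True)
class OrfResult:
    """The longest open reading frame of one transcript."""

    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2 offset on the reading strand
    nt_start: int  # 0-based half-open, forward strand
    nt_end: int
    peptide: ProteinRecord
    has_start: bool
    has_stop: bool
    transcript_length: int

    @property
    def aa_len(self) -> int:
        return len(self.peptide.seq)

    @property
    def coverage_fraction(self) -> float:
        return (self.nt_end - self.nt_start) / self.transcript_length


def six_frame_translate(rec: SeqRecord) -> list[str]:
    """Peptides of frames +0,+1,+2,-0,-1,-2 (standard code, '*' for stops,
    N-containing codons as 'X', trailing partial codons dropped)."""
    if len(rec.seq) < 3:
        raise ValueError(f"{rec.id}: sequence shorter than one codon")
    out = []
    for strand_seq in (rec.seq, revcomp(rec.seq)):
        for f in range(3):
            sub = strand_seq[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            out.append(str(Seq(sub).translate()) if sub else "")
    return out


def longest_orf(rec: SeqRecord) -> OrfResult:
    """Longest stop-free codon stretch over all six frames.

    Stretch length is the nucleotide span, with the terminating stop codon
    (when present) included in the span but excluded from the peptide; so a
    start..stop reading beats a same-span stop-less reading only through the
    tie-break.  Ties are broken by strand ('+' before '-'), then lower frame,
    then lower forward-strand start.  A transcript whose every frame is
    wall-to-wall stops yields a degenerate zero-length result.
    """
    peptides = six_frame_translate(rec)
    n = len(rec.seq)
    best = None
    for idx, pep in enumerate(peptides):
        strand = "+" if idx < 3 else "-"
        frame = idx % 3
        # stop-free stretches as [a, b) codon intervals
        a = 0
        for b in [i for i, c in enumerate(pep) if c == "*"] + [len(pep)]:
            seg_len = b - a
            has_stop = b < len(pep)
            # reading-strand nt coords (stop codon included in span if present)
            r_start = frame + 3 * a
            r_end = frame + 3 * (b + (1 if has_stop else 0))
            if strand == "+":
                nt_start, nt_end = r_start, r_end
            else:
                nt_start, nt_end = n - r_end, n - r_start
            cand = (
                -(r_end - r_start),
                0 if strand == "+" else 1,
                frame,
                nt_start,
                (pep[a:b], has_stop, r_start, r_end, strand, frame),
            )
            if best is None or cand[:4] < best[:4]:
                best = cand
            a = b + 1
    pep_seq, has_stop, r_start, r_end, strand, frame = best[4]
    if strand == "+":
        nt_start, nt_end = r_start, r_end
    else:
        nt_start, nt_end = n - r_end, n - r_start
    return OrfResult(
        transcript_id=rec.id,
        strand=strand,
        frame=frame,
        nt_start=nt_start,
        nt_end=nt_end,
        peptide=ProteinRecord(rec.id, pep_seq, source_transcript=rec.id),
        has_start=pep_seq.startswith("M"),
        has_stop=has_stop,
        transcript_length=n,
    )


def full_length_filter(orfs: list[OrfResult], min_aa: int = 100) -> list[OrfResult]:
    """ORFs with both start and stop codons and strictly more than ``min_aa``
    residues."""
    return [o for o in orfs if o.has_start and o.has_stop and o.aa_len > min_aa]


def coverage_profile(orfs: list[OrfResult], bins: int = 20,
                     threshold: float = 0.95) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of ORF coverage fractions plus the count at/above ``threshold``.

    Returns (counts, bin_edges, n_ge_threshold).
    """
    fracs = np.array([o.coverage_fraction for o in orfs], dtype=float)
    counts, edges = np.histogram(fracs, bins=bins, range=(0.0, 1.0))
    return counts, edges, int((fracs >= threshold).sum())


def long_transcript_short_orf(orfs: list[OrfResult], min_nt: int = 1000,
                              max_aa: int = 100) -> list[OrfResult]:
    """Long transcripts (>= ``min_nt``) encoding ORFs shorter than ``max_aa``
    residues — putative non-coding or pseudogenized transcripts."""
    return [o for o in orfs if o.transcript_length >= min_nt and o.aa_len < max_aa]


def orf_table(orfs: list[OrfResult]):
    """ORF results as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        dict(
            transcript_id=o.transcript_id, strand=o.strand, frame=o.frame,
            nt_start=o.nt_start, nt_end=o.nt_end, aa_len=o.aa_len,
            has_start=o.has_start, has_stop=o.has_stop,
            coverage=round(o.coverage_fraction, 4),
        )
        for o in orfs
    )
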