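"""Redundancy index, gene-number estimation, coding-length comparison and
saturation analysis.

The redundancy index (RI) of a coding-sequence dataset is the mean number of
high-identity within-dataset alignment hits per query (self hit included, so
a fully non-redundant dataset has RI = 1).  Dividing the dataset size by the
RI yields a rough estimate of the number of distinct genes.

The saturation analysis maps nested random subsamples of reads to a
reference transcriptome and counts how many reference sequences reach a
given number of mapped reads as depth grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from . import aligner
from .aligner import SearchParams, SequenceDatabase
from .core_io import SeqRecord, revcomp


@dataclass
class RIParams:
    """Search thresholds of the redundancy-index computation."""

    min_identity_pct: float = 98.0
    max_evalue: float = 1e-30
    max_hits: int = 250
    soft_mask_search: bool = True

    def to_search_params(self) -> SearchParams:
        return SearchParams(
            min_identity_pct=self.min_identity_pct,
            max_evalue=self.max_evalue,
            max_hits_per_query=self.max_hits,
            soft_mask=self.soft_mask_search,
        )


@dataclass(frozen=True)
class SaturationRow:
    fraction: float
    n_reads: int
    refs_ge1: int
    refs_ge100: int


def redundancy_index(coding_seqs: list[SeqRecord],
                     params: RIParams | None = None,
                     return_counts: bool = False):
    """Average number of within-dataset hits per query coding sequence.

    Queries are coding (ORF) sequences, not full-length transcripts, which
    suppresses biases from UTRs, vector remnants and leader sequences.  The
    search is soft-masked and capped at ``max_hits`` alignments per query.
    """
    if not coding_seqs:
        raise ValueError("redundancy index of an empty dataset is undefined")
    params = params or RIParams()
    sp = params.to_search_params()
    db = SequenceDatabase(coding_seqs, sp)
    counts = {rec.id: len(aligner.search(rec, db)) for rec in coding_seqs}
    ri = float(np.mean(list(counts.values())))
    if return_counts:
        return ri, counts
    return ri


def gene_number_estimate(n_sequences: int, ri: float) -> float:
    """Estimated number of distinct genes: dataset size divided by its RI."""
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if ri < 1:
        raise ValueError("a redundancy index below 1 is not meaningful")
    return n_sequences / ri


CLASS_GE100 = ">=100%"
CLASS_75_99 = "75-99%"
CLASS_LT75 = "<75%"
CLASS_UNMATCHED = "unmatched"


def coding_length_compare(
    reference_cds: list[SeqRecord],
    test_cds: list[SeqRecord],
    min_aln_nt: int = 100,
    min_identity_pct: float = 95.0,
) -> tuple[pd.DataFrame, float]:
    """Compare coding lengths of a test dataset against reference sequences.

    For each reference sequence the best-scoring *gap-free* hit in the test
    set with an uninterrupted alignment longer than ``min_aln_nt`` at or
    above ``min_identity_pct`` identity is taken to represent the same
    coding unit; the test/reference length ratio is classified into
    >=100%, 75-99% or <75%.  References with no qualifying hit are
    "unmatched".  Returns (per-reference table, matched percentage).
    """
    sp = SearchParams(min_identity_pct=min_identity_pct, soft_mask=False,
                      max_evalue=1e6, max_hits_per_query=10_000)
    db = SequenceDatabase(test_cds, sp)
    by_id = {t.id: t for t in test_cds}
    rows = []
    n_matched = 0
    for ref in reference_cds:
        best = None
        for hit in aligner.search(ref, db):
            if hit.gaps == 0 and hit.aln_len > min_aln_nt:
                best = hit  # hits are score-sorted; first qualifying wins
                break
        if best is None:
            rows.append(dict(reference_id=ref.id, hit_id=None, ratio=np.nan,
                             length_class=CLASS_UNMATCHED))
            continue
        n_matched += 1
        ratio = len(by_id[best.subject_id].seq) / len(ref.seq)
        if ratio >= 1.0:
            cls = CLASS_GE100
        elif ratio >= 0.75:
            cls = CLASS_75_99
        else:
            cls = CLASS_LT75
        rows.append(dict(reference_id=ref.id, hit_id=best.subject_id,
                         ratio=round(ratio, 4), length_class=cls))
    table = pd.DataFrame(rows, columns=["reference_id", "hit_id", "ratio", "length_class"])
    matched_pct = 100.0 * n_matched / len(reference_cds) if reference_cds else 0.0
    return table, matched_pct


class ReadMapper:
    """Near-exact read mapper over a reference set.

    Candidate references are selected through the aligner's word index; each
    candidate is verified by exact edit-distance alignment of the read
    against the reference (both strands), accepting the best placement with
    at most ``max_divergence`` errors per read base.  This is the fast
    exact/near-exact mode of the internal alignment machinery used for
    saturation mapping.
    """

    def __init__(self, reference: list[SeqRecord], word_size: int = 11,
                 max_divergence: float = 0.05):
        self.reference = list(reference)
        self.max_divergence = max_divergence
        self._db = SequenceDatabase(reference, SearchParams(word_size=word_size))

    def map_read(self, read: SeqRecord) -> str | None:
        """Reference id of the best placement, or None if unmapped."""
        limit = int(self.max_divergence * len(read.seq))
        best: tuple[int, str] | None = None
        for idx, strands in self._db.candidates(read).items():
            ref = self.reference[idx]
            for strand in strands:
                target = ref.seq if strand == "+" else revcomp(ref.seq)
                res = edlib.align(read.seq, target, mode="HW", task="distance", k=limit)
                d = res["editDistance"]
                if d != -1 and (best is None or (d, ref.id) < best):
                    best = (d, ref.id)
        return best[1] if best else None


def saturation_curve(
    reads: list[SeqRecord],
    reference: list[SeqRecord],
    fractions: list[float],
    hit_thresholds: tuple[int, int] = (1, 100),
    seed: int = 0,
    mapper: ReadMapper | None = None,
) -> list[SaturationRow]:
    """Reference detection as a function of sequencing depth.

    A single seeded permutation of the reads is prefix-sliced to obtain
    *nested* subsamples (sampling without replacement), so the detection
    counts are monotone in the sampled fraction by construction.
    """
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    mapper = mapper or ReadMapper(reference)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    assignments = [mapper.map_read(reads[i]) for i in order]
    t1, t2 = hit_thresholds
    rows = []
    for frac in sorted(fractions):
        n = int(round(frac * len(reads)))
        counts: dict[str, int] = {}
        for ref_id in assignments[:n]:
            if ref_id is not None:
                counts[ref_id] = counts.get(ref_id, 0) + 1
        rows.append(
            SaturationRow(
                fraction=frac,
                n_reads=n,
                refs_ge1=sum(1 for c in counts.values() if c >= t1),
                refs_ge100=sum(1 for c in counts.values() if c >= t2),
            )
        )
    return rows


def expected_occupancy(n_refs: int, n_reads: int) -> float:
    """Expected number of references hit at least once when ``n_reads`` fall
    uniformly and independently on ``n_refs`` references."""
    return n_refs * (1.0 - (1.0 - 1.0 / n_refs) ** n_reads)


def saturation_table(rows: list[SaturationRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
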