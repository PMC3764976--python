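"""Seed-and-extend local alignment engine for nucleotides and proteins.

This module stands in for megablast/BlastN+/BlastP+ in every downstream
stage.  The search strategy is classic seed-and-extend:

1. *Seeding* — exact shared words (``word_size``-mers; for proteins, words
   over a reduced 10-letter alphabet) select candidate subjects and, for
   nucleotides, the strand.  With soft masking enabled, words overlapping
   low-complexity intervals are never used as seeds.
2. *Extension* — each candidate pair is extended by full optimal local
   dynamic programming (affine gaps), so the reported top hit is exactly the
   Smith-Waterman optimum for the pair under the configured scoring.
   Extension ignores the soft mask: masked stretches are scored normally.

E-values follow the Karlin-Altschul form ``E = K * m * n * exp(-lambda * S)``
with constants fixed per scoring scheme; they gate hits, they are not
calibrated against any external tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import ProteinRecord, SeqRecord, revcomp

# Karlin-Altschul constants per scoring scheme (fixed, documented; see module
# docstring).  Keys: "nt" for +1/-2 match/mismatch, "aa" for BLOSUM62.
KA_PARAMS = {"nt": (1.28, 0.46), "aa": (0.267, 0.041)}

# Murphy 10-letter reduced amino-acid alphabet used for protein seeding.
_MURPHY10 = {}
for group in ("LVIM", "C", "A", "G", "ST", "P", "FYW", "EDNQ", "KR", "H"):
    for aa in group:
        _MURPHY10[aa] = group[0]


@dataclass
class SearchParams:
    """Scoring and filtering parameters for :func:`local_align` / :func:`search`.

    Defaults are megablast-like for nucleotides.  Use
    :func:`SearchParams.protein` for BLOSUM62 protein search.
    """

    word_size: int = 11
    min_identity_pct: float = 0.0
    max_evalue: float = 10.0
    max_hits_per_query: int = 250
    soft_mask: bool = False
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    is_protein: bool = False
    # entropy mask tuning (bits over a sliding window)
    mask_window: int = 12
    mask_threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.max_hits_per_query < 1:
            raise ValueError("max_hits_per_query must be >= 1")

    @classmethod
    def protein(cls, **kw) -> "SearchParams":
        defaults = dict(
            word_size=4,
            is_protein=True,
            gap_open=-11,
            gap_extend=-1,
            mask_window=12,
            mask_threshold=2.2,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject.

    Coordinates are 0-based half-open on the forward strands of both
    sequences; ``identity_pct`` counts matches over all alignment columns
    (a gap column is a non-match, and N matches nothing, including N).
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # '+' or '-' (nucleotide; '+' for protein)
    aln_len: int
    identity_pct: float
    gaps: int
    score: float
    evalue: float = math.inf

    def __post_init__(self) -> None:
        assert self.q_end > self.q_start and self.s_end > self.s_start
        assert 0.0 <= self.identity_pct <= 100.0
        assert self.aln_len >= max(self.q_end - self.q_start, self.s_end - self.s_start)


def shannon_entropy(seq: str) -> float:
    """Shannon entropy (bits/symbol) of the character composition of ``seq``."""
    if not seq:
        return 0.0
    counts = {}
    for c in seq:
        counts[c] = counts.get(c, 0) + 1
    n = len(seq)
    return -sum((k / n) * math.log2(k / n) for k in counts.values())


def soft_mask(seq: str, window: int = 12, threshold: float = 1.5) -> list[tuple[int, int]]:
    """Low-complexity intervals: windows whose entropy falls below ``threshold``.

    Returns merged 0-based half-open intervals.  Sequences shorter than the
    window are assessed as a single window.
    """
    n = len(seq)
    if n == 0:
        return []
    if n <= window:
        return [(0, n)] if shannon_entropy(seq) < threshold else []
    flagged: list[tuple[int, int]] = []
    for i in range(n - window + 1):
        if shannon_entropy(seq[i : i + window]) < threshold:
            if flagged and i <= flagged[-1][1]:
                flagged[-1] = (flagged[-1][0], i + window)
            else:
                flagged.append((i, i + window))
    return flagged


def evalue(score: float, query_len: int, db_len: int, params: SearchParams) -> float:
    """Karlin-Altschul expectation ``K * m * n * exp(-lambda * S)``."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    lam, k = KA_PARAMS["aa" if params.is_protein else "nt"]
    return k * query_len * db_len * math.exp(-lam * score)


@lru_cache(maxsize=8)
def _nt_matrix(match: int, mismatch: int):
    """ACGTN matrix: N mismatches everything, including N."""
    m = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            m[x, y] = float(match) if (x == y and x != "N") else float(mismatch)
    return m


@lru_cache(maxsize=4)
def _aa_matrix():
    """BLOSUM62 extended so that X/* score -4 against everything."""
    b62 = substitution_matrices.load("BLOSUM62")
    alpha = "ARNDCQEGHILKMFPSTWYVX*"
    m = substitution_matrices.Array(alpha, dims=2)
    for x in alpha:
        for y in alpha:
            if x in "X*" or y in "X*":
                m[x, y] = -4.0
            else:
                m[x, y] = float(b62[x, y])
    return m


def _make_pairwise(params: SearchParams, mode: str = "local") -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _aa_matrix() if params.is_protein else _nt_matrix(
        params.match, params.mismatch
    )
    al.open_gap_score = float(params.gap_open)
    al.extend_gap_score = float(params.gap_extend)
    return al


def alignment_stats(alignment, protein: bool = False) -> tuple[int, int, int]:
    """(matches, gap_columns, alignment_columns) for a Bio.Align alignment.

    N (nucleotide) and X (protein) never count as matches.
    """
    coords = alignment.coordinates
    qseq = alignment.sequences[0]
    sseq = alignment.sequences[1]
    wildcard = "X" if protein else "N"
    matches = 0
    gap_cols = 0
    total = 0
    for k in range(coords.shape[1] - 1):
        q0, q1 = int(coords[0, k]), int(coords[0, k + 1])
        s0, s1 = int(coords[1, k]), int(coords[1, k + 1])
        if q1 > q0 and s1 > s0:
            total += q1 - q0
            for a, b in zip(qseq[q0:q1], sseq[s0:s1]):
                if a == b and a != wildcard:
                    matches += 1
        else:
            span = (q1 - q0) + (s1 - s0)
            gap_cols += span
            total += span
    return matches, gap_cols, total


def _kmer_set(seq: str, word: int, protein: bool, mask: Sequence[tuple[int, int]] | None) -> set[str]:
    """Exact words of length ``word`` not overlapping masked intervals.

    For proteins, words are projected to the Murphy 10-letter alphabet.
    Words containing N (nt) are skipped.
    """
    masked = np.zeros(len(seq), dtype=bool)
    if mask:
        for a, b in mask:
            masked[a:b] = True
    out: set[str] = set()
    for i in range(len(seq) - word + 1):
        if mask and masked[i : i + word].any():
            continue
        w = seq[i : i + word]
        if protein:
            try:
                w = "".join(_MURPHY10[c] for c in w)
            except KeyError:
                continue
        elif "N" in w:
            continue
        out.add(w)
    return out


def _seq_mask(seq: str, params: SearchParams) -> list[tuple[int, int]] | None:
    if not params.soft_mask:
        return None
    return soft_mask(seq, params.mask_window, params.mask_threshold)


def _extend(query: SeqRecord | ProteinRecord, subject, sseq_oriented: str, strand: str,
            params: SearchParams) -> AlignmentHit | None:
    """Full optimal local DP on an oriented pair; map coords back to forward."""
    engine = _make_pairwise(params)
    alns = engine.align(query.seq, sseq_oriented)
    try:
        best = alns[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    matches, gap_cols, total = alignment_stats(best, params.is_protein)
    if total == 0:
        return None
    coords = best.coordinates
    q_start, q_end = int(coords[0, 0]), int(coords[0, -1])
    s_start, s_end = int(coords[1, 0]), int(coords[1, -1])
    if strand == "-":
        slen = len(subject.seq)
        s_start, s_end = slen - s_end, slen - s_start
    if q_end == q_start or s_end == s_start:
        return None
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        strand=strand,
        aln_len=total,
        identity_pct=100.0 * matches / total,
        gaps=gap_cols,
        score=float(best.score),
    )


def local_align(query, subject, params: SearchParams | None = None) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of one query against one subject.

    Returns the best hit per candidate strand (both strands for nucleotides),
    sorted by descending score.  No shared seed word -> empty list.
    """
    params = params or SearchParams()
    if not query.seq or not subject.seq:
        raise ValueError("cannot align empty sequences")
    qmask = _seq_mask(query.seq, params)
    smask = _seq_mask(subject.seq, params)
    qk = _kmer_set(query.seq, params.word_size, params.is_protein, qmask)
    sk = _kmer_set(subject.seq, params.word_size, params.is_protein, smask)
    hits: list[AlignmentHit] = []
    if qk & sk:
        hit = _extend(query, subject, subject.seq, "+", params)
        if hit:
            hits.append(hit)
    if not params.is_protein:
        rc = revcomp(subject.seq)
        rcmask = None
        if smask is not None:
            n = len(subject.seq)
            rcmask = [(n - b, n - a) for a, b in reversed(smask)]
        rck = _kmer_set(rc, params.word_size, False, rcmask)
        if qk & rck:
            hit = _extend(query, subject, rc, "-", params)
            if hit:
                hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.strand))
    return hits


class SequenceDatabase:
    """A searchable set of records with a word index built once.

    The index maps each seed word to the subjects containing it (forward and,
    for nucleotides, reverse-complement orientation tracked separately).
    """

    def __init__(self, records: Sequence, params: SearchParams | None = None):
        self.params = params or SearchParams()
        self.records = list(records)
        self.total_length = sum(len(r.seq) for r in self.records)
        self._fwd: dict[str, set[int]] = {}
        self._rev: dict[str, set[int]] = {}
        w = self.params.word_size
        prot = self.params.is_protein
        for idx, rec in enumerate(self.records):
            mask = _seq_mask(rec.seq, self.params)
            for word in _kmer_set(rec.seq, w, prot, mask):
                self._fwd.setdefault(word, set()).add(idx)
            if not prot:
                rc = revcomp(rec.seq)
                rcmask = None
                if mask is not None:
                    n = len(rec.seq)
                    rcmask = [(n - b, n - a) for a, b in reversed(mask)]
                for word in _kmer_set(rc, w, False, rcmask):
                    self._rev.setdefault(word, set()).add(idx)

    def candidates(self, query) -> dict[int, set[str]]:
        """Subject indices sharing at least one unmasked seed word, by strand."""
        qmask = _seq_mask(query.seq, self.params)
        qk = _kmer_set(query.seq, self.params.word_size, self.params.is_protein, qmask)
        out: dict[int, set[str]] = {}
        for word in qk:
            for idx in self._fwd.get(word, ()):
                out.setdefault(idx, set()).add("+")
            for idx in self._rev.get(word, ()):
                out.setdefault(idx, set()).add("-")
        return out


def search(query, database, params: SearchParams | None = None) -> list[AlignmentHit]:
    """Search a query against a database (list of records or SequenceDatabase).

    Best hit per subject is retained, filtered by ``min_identity_pct`` /
    ``max_evalue``, sorted by descending score then ascending subject id, and
    truncated to ``max_hits_per_query``.
    """
    if isinstance(database, SequenceDatabase):
        db = database
        params = params or db.params
    else:
        params = params or SearchParams()
        db = SequenceDatabase(database, params)
    if not db.records:
        return []
    hits: list[AlignmentHit] = []
    for idx, strands in db.candidates(query).items():
        subject = db.records[idx]
        best: AlignmentHit | None = None
        for strand in sorted(strands):
            oriented = subject.seq if strand == "+" else revcomp(subject.seq)
            hit = _extend(query, subject, oriented, strand, params)
            if hit and (best is None or hit.score > best.score):
                best = hit
        if best is None:
            continue
        best = replace(best, evalue=evalue(best.score, len(query.seq), db.total_length, params))
        if best.identity_pct >= params.min_identity_pct and best.evalue <= params.max_evalue:
            hits.append(best)
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits[: params.max_hits_per_query]


def hits_to_tsv(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits as BLAST outfmt-6-like TSV (1-based inclusive coordinates)."""
    cols = "qid sid pident length mismatch gapopen qstart qend sstart send evalue score"
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols.split()) + "\n")
        for h in hits:
            matches = round(h.identity_pct * h.aln_len / 100.0)
            mism = h.aln_len - matches - h.gaps
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.identity_pct:.2f}", h.aln_len,
                        mism, h.gaps, h.q_start + 1, h.q_end, h.s_start + 1, h.s_end,
                        f"{h.evalue:.2e}", f"{h.score:.1f}",
                    )
                )
                + "\n"
            )
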