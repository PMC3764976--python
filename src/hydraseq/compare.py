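"""Dataset-versus-dataset comparisons: only-sets, contaminant screening,
genome support and pseudogene classification.

An "only-set" is the set of sequences of one dataset without a >= 95%
identity counterpart in another (e.g. RNAseq-only transcripts missing from
genome-predicted transcriptomes, and vice versa).  Candidate pseudogenes are
transcripts whose longest ORF is short and does not span the transcript,
which align perfectly and gap-free to the genome, and which have no good
match among predicted transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import aligner
from .aligner import SearchParams, SequenceDatabase, soft_mask
from .core_io import SeqRecord, revcomp
from .orftools import OrfResult


@dataclass
class OnlySetResult:
    query_id: str
    status: str  # "shared" or "only"
    best_identity_pct: float | None
    evidence_tags: set = field(default_factory=set)


@dataclass(frozen=True)
class PseudogeneCall:
    transcript_id: str
    orf_aa_len: int
    orf_spans_full: bool
    genome_perfect: bool
    max_identity_to_predicted_pct: float | None
    is_pseudogene_candidate: bool


def _permissive_params() -> SearchParams:
    # identity reported for the best hit regardless of threshold; masking off
    return SearchParams(min_identity_pct=0.0, soft_mask=False, max_evalue=1e-3,
                        max_hits_per_query=10_000)


def _best_identity(query: SeqRecord, db: SequenceDatabase) -> float | None:
    hits = aligner.search(query, db)
    if not hits:
        return None
    return max(h.identity_pct for h in hits)


def find_only_set(
    queries: list[SeqRecord],
    subjects: list[SeqRecord],
    identity_threshold: float = 95.0,
) -> list[OnlySetResult]:
    """Flag queries without a >= ``identity_threshold`` hit among subjects.

    Low-complexity masking is disabled for this comparison.  Run the
    symmetric direction separately for the reverse only-set.
    """
    db = SequenceDatabase(subjects, _permissive_params())
    out = []
    for q in queries:
        best = _best_identity(q, db)
        status = "shared" if best is not None and best >= identity_threshold else "only"
        out.append(OnlySetResult(q.id, status, best))
    return out


def evidence_annotate(
    only_results: list[OnlySetResult],
    queries: list[SeqRecord],
    evidence_datasets: dict[str, list[SeqRecord]],
    identity_threshold: float = 95.0,
) -> list[OnlySetResult]:
    """Tag each only-sequence with every evidence dataset containing a hit.

    Sequences with an empty tag set are novel.
    """
    by_id = {q.id: q for q in queries}
    dbs = {
        name: SequenceDatabase(records, _permissive_params())
        for name, records in evidence_datasets.items()
    }
    out = []
    for res in only_results:
        tags = set(res.evidence_tags)
        if res.status == "only":
            q = by_id[res.query_id]
            for name, db in dbs.items():
                best = _best_identity(q, db)
                if best is not None and best >= identity_threshold:
                    tags.add(name)
        out.append(OnlySetResult(res.query_id, res.status, res.best_identity_pct, tags))
    return out


LOW_COMPLEXITY = "low_complexity"
CLEAN = "clean"


def contaminant_screen(
    queries: list[SeqRecord],
    contaminant_dbs: list[tuple[str, list[SeqRecord]]],
    low_complexity_first: bool = True,
    identity_threshold: float = 95.0,
    max_evalue: float = 1e-10,
    mask_coverage: float = 0.80,
) -> dict[str, str]:
    """Sequential contaminant assignment.

    Each query receives the label of the FIRST database it hits (sequences
    found in one database are not realigned to the next); queries whose
    low-complexity mask covers >= ``mask_coverage`` of their length are
    labelled first when ``low_complexity_first``.  Unassigned queries are
    "clean" — the result is a partition.
    """
    assignments: dict[str, str] = {}
    survivors = list(queries)
    if low_complexity_first:
        rest = []
        for q in survivors:
            masked = sum(b - a for a, b in soft_mask(q.seq))
            if masked >= mask_coverage * len(q.seq):
                assignments[q.id] = LOW_COMPLEXITY
            else:
                rest.append(q)
        survivors = rest
    sp = SearchParams(min_identity_pct=identity_threshold, max_evalue=max_evalue,
                      soft_mask=False, max_hits_per_query=1)
    for name, records in contaminant_dbs:
        db = SequenceDatabase(records, sp)
        rest = []
        for q in survivors:
            if aligner.search(q, db):
                assignments[q.id] = name
            else:
                rest.append(q)
        survivors = rest
    for q in survivors:
        assignments[q.id] = CLEAN
    return assignments


def genome_support(
    transcripts: list[SeqRecord],
    genome: list[SeqRecord],
    min_identity_pct: float = 75.0,
) -> pd.DataFrame:
    """Best genomic hit per transcript; supported iff identity exceeds the
    threshold.  Returns columns (transcript_id, supported, identity_pct)."""
    db = SequenceDatabase(genome, _permissive_params())
    rows = []
    for t in transcripts:
        best = _best_identity(t, db)
        rows.append(
            dict(
                transcript_id=t.id,
                supported=best is not None and best > min_identity_pct,
                identity_pct=None if best is None else round(best, 2),
            )
        )
    return pd.DataFrame(rows, columns=["transcript_id", "supported", "identity_pct"])


def _perfect_genome_match(t: SeqRecord, genome: list[SeqRecord]) -> bool:
    """A single gap-free 100%-identity alignment covering the whole transcript.

    Such an alignment exists exactly when the transcript occurs verbatim in a
    contig on either strand, so this is an exact substring test, not a
    heuristic shortcut.
    """
    rc = None
    for contig in genome:
        if t.seq in contig.seq:
            return True
        if rc is None:
            rc = revcomp(t.seq)
        if rc in contig.seq:
            return True
    return False


def pseudogene_classify(
    transcripts: list[SeqRecord],
    orfs: dict[str, OrfResult],
    genome: list[SeqRecord],
    predicted_set: list[SeqRecord],
    max_aa: int = 100,
    span_threshold: float = 0.95,
    predicted_identity_threshold: float = 95.0,
) -> list[PseudogeneCall]:
    """Classify transcripts as pseudogene candidates.

    Candidate iff the longest ORF is shorter than ``max_aa`` residues AND
    does not span >= ``span_threshold`` of the transcript AND the transcript
    aligns to the genome with 100% identity and zero gaps over its full
    length AND its best identity to any predicted transcript is below
    ``predicted_identity_threshold``.
    """
    pred_db = SequenceDatabase(predicted_set, _permissive_params())
    calls = []
    for t in transcripts:
        orf = orfs[t.id]
        spans_full = orf.coverage_fraction >= span_threshold
        short_orf = orf.aa_len < max_aa
        if not short_orf or spans_full:
            calls.append(PseudogeneCall(t.id, orf.aa_len, spans_full, False, None, False))
            continue
        perfect = _perfect_genome_match(t, genome)
        if not perfect:
            calls.append(PseudogeneCall(t.id, orf.aa_len, spans_full, False, None, False))
            continue
        best_pred = _best_identity(t, pred_db)
        candidate = best_pred is None or best_pred < predicted_identity_threshold
        calls.append(
            PseudogeneCall(t.id, orf.aa_len, spans_full, True, best_pred, candidate)
        )
    return calls


def pseudogene_table(calls: list[PseudogeneCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
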