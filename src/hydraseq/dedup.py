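"""Redundancy removal: keep one longest unique ORF per gene.

Pipeline: the longest ORF of each transcript is extracted; peptides shorter
than 50 aa are dropped; 25 C-terminal residues are trimmed (the nonsense tail
translated after a frameshift is short, so trimming suppresses that noise);
the trimmed peptides are clustered greedily at 95% global identity keeping
the longest member of each cluster; the cluster representatives are then
searched all-vs-all and a representative ("match") is discarded when a longer
query reproduces it under six criteria:

  i)   the alignment spans at least 25 aa and is not a self match,
  ii)  the query is strictly longer than the match,
  iii) the best alignment block identity exceeds 95%,
  iv)  the alignment contains no gap columns (so splice variants survive),
  v)   the alignment covers at least 95% of the match,
  vi)  at most 100 residues of the match lie outside the alignment.

Finally the *untruncated* transcripts/peptides of the survivors are restored:
the C-terminal trim exists only inside the clustering and filtering stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from . import aligner
from .aligner import SearchParams, SequenceDatabase, _aa_matrix, alignment_stats
from .core_io import ProteinRecord, SeqRecord
from .orftools import OrfResult, longest_orf


@dataclass
class DedupParams:
    min_aa: int = 50
    cterm_trim: int = 25
    cluster_identity: float = 0.95
    gap_penalty: int = 20
    min_aln_aa: int = 25
    min_block_identity: float = 0.95
    min_match_span: float = 0.95
    max_unmatched_aa: int = 100


@dataclass(frozen=True)
class DiscardDecision:
    """Outcome of testing one (query, match) representative pair."""

    query_id: str
    match_id: str
    kept: bool
    failed_criterion: str  # criterion that saved the match, or "discarded"


def global_identity(p1: str, p2: str, gap_penalty: int = 20) -> float:
    """End-to-end alignment identity: matches / alignment columns.

    The alignment path is scored with BLOSUM62 substitutions and a linear
    penalty of ``gap_penalty`` per gap column.
    """
    if not p1 or not p2:
        raise ValueError("cannot align empty protein sequences")
    eng = Align.PairwiseAligner()
    eng.mode = "global"
    eng.substitution_matrix = _aa_matrix()
    eng.open_gap_score = float(-gap_penalty)
    eng.extend_gap_score = float(-gap_penalty)
    best = eng.align(p1, p2)[0]
    matches, _, total = alignment_stats(best, protein=True)
    return 100.0 * matches / total


def cluster_proteins(proteins: list[ProteinRecord],
                     params: DedupParams | None = None) -> list[list[ProteinRecord]]:
    """Greedy centroid clustering, longest-first.

    Each sequence joins the first centroid with global identity at or above
    the threshold, else founds a new cluster; the centroid (longest member,
    processed first) is the representative.
    """
    params = params or DedupParams()
    ordered = sorted(proteins, key=lambda p: (-len(p.seq), p.id))
    clusters: list[list[ProteinRecord]] = []
    for prot in ordered:
        for cluster in clusters:
            centroid = cluster[0]
            if global_identity(prot.seq, centroid.seq, params.gap_penalty) >= 100.0 * params.cluster_identity:
                cluster.append(prot)
                break
        else:
            clusters.append([prot])
    return clusters


def _judge(query: ProteinRecord, match: ProteinRecord, hit, params: DedupParams) -> str:
    """First criterion that saves ``match`` from being discarded, else "discarded"."""
    if hit is None or hit.aln_len < params.min_aln_aa:
        return "aln_too_short"
    if query.id == match.id:
        return "self"
    if len(query.seq) <= len(match.seq):
        return "query_not_bigger"
    if hit.identity_pct <= 100.0 * params.min_block_identity:
        return "identity_low"
    if hit.gaps > 0:
        return "has_gaps"
    span = hit.s_end - hit.s_start
    if span < params.min_match_span * len(match.seq):
        return "span_low"
    if len(match.seq) - span > params.max_unmatched_aa:
        return "unmatched_high"
    return "discarded"


def redundancy_filter(
    representatives: list[ProteinRecord], params: DedupParams | None = None
) -> tuple[list[ProteinRecord], list[DiscardDecision]]:
    """All-vs-all search over representatives; discard matches reproduced by
    longer queries under criteria i-vi.  Low-complexity masking is disabled."""
    params = params or DedupParams()
    search_params = SearchParams.protein(soft_mask=False, max_evalue=1e6,
                                         max_hits_per_query=10_000)
    db = SequenceDatabase(representatives, search_params)
    by_id = {p.id: p for p in representatives}
    decisions: list[DiscardDecision] = []
    discarded: set[str] = set()
    for query in representatives:
        for hit in aligner.search(query, db):
            match = by_id[hit.subject_id]
            if match.id == query.id:
                continue
            verdict = _judge(query, match, hit, params)
            kept = verdict != "discarded"
            decisions.append(DiscardDecision(query.id, match.id, kept, verdict))
            if not kept:
                discarded.add(match.id)
    kept = [p for p in representatives if p.id not in discarded]
    return kept, decisions


def deduplicate(
    transcripts: list[SeqRecord], params: DedupParams | None = None
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Full redundancy-removal pipeline on nucleotide transcripts.

    Returns the kept (untruncated) transcripts and a per-transcript report
    with the removal stage and reason.
    """
    params = params or DedupParams()
    rows = []
    orfs: dict[str, OrfResult] = {t.id: longest_orf(t) for t in transcripts}

    surviving: list[ProteinRecord] = []
    for t in transcripts:
        orf = orfs[t.id]
        if orf.aa_len < params.min_aa:
            rows.append(dict(id=t.id, kept=False, stage="length", reason="min_aa"))
            continue
        trimmed = orf.peptide.seq[: len(orf.peptide.seq) - params.cterm_trim]
        surviving.append(ProteinRecord(t.id, trimmed, source_transcript=t.id))

    clusters = cluster_proteins(surviving, params)
    reps = []
    for cluster in clusters:
        reps.append(cluster[0])
        for member in cluster[1:]:
            rows.append(dict(id=member.id, kept=False, stage="cluster",
                             reason=f"clustered_with:{cluster[0].id}"))

    kept_reps, decisions = redundancy_filter(reps, params)
    kept_ids = {p.id for p in kept_reps}
    discarders = {}
    for d in decisions:
        if not d.kept and d.match_id not in discarders:
            discarders[d.match_id] = d.query_id
    for rep in reps:
        if rep.id not in kept_ids:
            rows.append(dict(id=rep.id, kept=False, stage="redundancy",
                             reason=f"redundant_with:{discarders.get(rep.id, '?')}"))

    by_id = {t.id: t for t in transcripts}
    kept_transcripts = [by_id[p.id] for p in sorted(kept_reps, key=lambda p: p.id)]
    for t in kept_transcripts:
        rows.append(dict(id=t.id, kept=True, stage="kept", reason=""))
    report = pd.DataFrame(rows, columns=["id", "kept", "stage", "reason"])
    return kept_transcripts, report
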