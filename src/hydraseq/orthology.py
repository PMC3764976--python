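"""Reciprocal-best-hit (RBH) ortholog detection between two proteomes.

A pair (a, b) is an RBH iff b is a's unique best-scoring hit in proteome B
and a is b's unique best-scoring hit in proteome A, both directions passing
the E-value gate.  A tie for the best score means the query has no unique
best and forms no pair.  The output is a partial matching: no id occurs in
more than one pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from . import aligner
from .aligner import SearchParams, SequenceDatabase
from .core_io import ProteinRecord


@dataclass(frozen=True)
class RbhPair:
    id_a: str
    id_b: str
    score_ab: float
    score_ba: float
    evalue_ab: float
    evalue_ba: float


def _unique_best(query, db: SequenceDatabase) -> aligner.AlignmentHit | None:
    hits = aligner.search(query, db)
    if not hits:
        return None
    if len(hits) > 1 and hits[1].score == hits[0].score:
        return None  # tied best: no unique best hit
    return hits[0]


def rbh(
    proteome_a: list[ProteinRecord],
    proteome_b: list[ProteinRecord],
    max_evalue: float = 1e-8,
    soft_mask: bool = True,
) -> list[RbhPair]:
    """Reciprocal best hits between two proteomes (soft-masked BLOSUM62
    search, E-value gated in both directions)."""
    if not proteome_a or not proteome_b:
        return []
    sp = SearchParams.protein(soft_mask=soft_mask, max_evalue=max_evalue)
    db_a = SequenceDatabase(proteome_a, sp)
    db_b = SequenceDatabase(proteome_b, sp)
    best_ab = {a.id: _unique_best(a, db_b) for a in proteome_a}
    best_ba = {b.id: _unique_best(b, db_a) for b in proteome_b}
    pairs = []
    for a in proteome_a:
        fwd = best_ab[a.id]
        if fwd is None:
            continue
        back = best_ba[fwd.subject_id]
        if back is None or back.subject_id != a.id:
            continue
        pairs.append(
            RbhPair(a.id, fwd.subject_id, fwd.score, back.score, fwd.evalue, back.evalue)
        )
    return pairs


def rbh_percentage(n_pairs: int, n_sequences: int) -> float:
    """Share of a sequence set with an RBH ortholog, as a percentage
    (one decimal, the convention used when reporting only-set orthology)."""
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    return round(100.0 * n_pairs / n_sequences, 1)


def rbh_subset(pairs: Iterable[RbhPair], id_subset: set[str]) -> list[RbhPair]:
    """Pairs whose A-side id belongs to ``id_subset`` (RBH is computed on
    whole proteomes first, then restricted to a sequence subset)."""
    return [p for p in pairs if p.id_a in id_subset]


def rbh_table(pairs: Iterable[RbhPair]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pairs])
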