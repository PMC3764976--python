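from __future__ import annotations

import math

import numpy as np
import pytest

from hydraseq.aligner import (
    SearchParams,
    SequenceDatabase,
    evalue,
    local_align,
    search,
    soft_mask,
)
from hydraseq.core_io import SeqRecord, revcomp

from conftest import mutate, random_nt
from oracles import nt_score_fn, shared_word, sw_align, sw_score


class TestLocalAlign:
    def test_self_alignment_is_perfect(self):
        rng = np.random.default_rng(1)
        rec = SeqRecord("q", random_nt(rng, 150))
        (hit,) = [h for h in local_align(rec, rec) if h.strand == "+"]
        assert hit.identity_pct == 100.0
        assert hit.gaps == 0
        assert hit.aln_len == 150
        assert (hit.q_start, hit.q_end) == (0, 150)

    def test_two_substitutions_match_full_smith_waterman(self):
        """A 100-nt pair with 2 substitutions: top hit equals the DP oracle."""
        rng = np.random.default_rng(2)
        q = SeqRecord("q", random_nt(rng, 100))
        s = SeqRecord("s", mutate(rng, q.seq, 2))
        hit = local_align(q, s)[0]
        score, matches, gaps, cols = sw_align(q.seq, s.seq, nt_score_fn(), -5.0, -2.0)
        assert hit.score == score
        assert hit.identity_pct == pytest.approx(100.0 * matches / cols)
        assert hit.identity_pct == 98.0

    def test_unrelated_pair_without_shared_word_yields_no_hit(self):
        rng = np.random.default_rng(3)
        a, b = random_nt(rng, 100), random_nt(rng, 100)
        # the oracle confirms the chosen seed gives no shared 11-mer either way
        assert not shared_word(a, b) and not shared_word(a, revcomp(b))
        assert local_align(SeqRecord("a", a), SeqRecord("b", b)) == []

    def test_reverse_complement_consistency(self):
        rng = np.random.default_rng(4)
        q = SeqRecord("q", random_nt(rng, 120))
        s = SeqRecord("s", mutate(rng, q.seq, 3))
        fwd = local_align(q, s)[0]
        rc = local_align(q, SeqRecord("src", revcomp(s.seq)))[0]
        assert rc.score == fwd.score
        assert rc.strand == "-"
        assert (rc.s_start, rc.s_end) == (len(s.seq) - fwd.s_end, len(s.seq) - fwd.s_start)

    def test_best_hit_score_is_symmetric(self):
        rng = np.random.default_rng(5)
        a = SeqRecord("a", random_nt(rng, 140))
        b = SeqRecord("b", mutate(rng, a.seq, 6))
        assert local_align(a, b)[0].score == local_align(b, a)[0].score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align(SeqRecord("a", "ACGT"), SeqRecord("b", "A").slice(0, 0))


class TestSearch:
    def test_self_in_database_is_top_hit(self):
        rng = np.random.default_rng(6)
        recs = [SeqRecord(f"r{i}", random_nt(rng, 120)) for i in range(5)]
        hits = search(recs[2], recs)
        assert hits[0].subject_id == "r2"
        assert hits[0].identity_pct == 100.0

    def test_hit_cap_at_250_alignments_per_query(self):
        """300 identical database copies: at most 250 alignments are kept."""
        rng = np.random.default_rng(7)
        q = SeqRecord("q", random_nt(rng, 100))
        db = [SeqRecord(f"c{i:03d}", q.seq) for i in range(300)]
        assert len(search(q, db, SearchParams(max_hits_per_query=250))) == 250

    def test_mixed_database_equals_brute_force_oracle(self):
        """Hit set matches all-pairs Smith-Waterman under the same scoring."""
        rng = np.random.default_rng(8)
        q = SeqRecord("q", random_nt(rng, 150))
        db = []
        for i in range(6):
            db.append(SeqRecord(f"rel{i}", mutate(rng, q.seq, int(rng.integers(0, 8)))))
        for i in range(6):
            db.append(SeqRecord(f"unrel{i}", random_nt(rng, 150)))
        params = SearchParams(max_evalue=1e6)
        hits = {h.subject_id: h for h in search(q, db, params)}
        fn = nt_score_fn()
        for rec in db:
            seeded = shared_word(q.seq, rec.seq) or shared_word(q.seq, revcomp(rec.seq))
            if not seeded:
                assert rec.id not in hits
                continue
            oracle = max(
                sw_score(q.seq, rec.seq, fn, -5.0, -2.0),
                sw_score(q.seq, revcomp(rec.seq), fn, -5.0, -2.0),
            )
            assert hits[rec.id].score == oracle

    def test_empty_database(self):
        assert search(SeqRecord("q", "ACGTACGTACGTACGT"), []) == []

    def test_results_sorted_and_filtered_by_identity(self):
        rng = np.random.default_rng(9)
        q = SeqRecord("q", random_nt(rng, 200))
        near = SeqRecord("near", mutate(rng, q.seq, 2))
        far = SeqRecord("far", mutate(rng, q.seq, 30))  # 85% identity
        hits = search(q, [far, near], SearchParams(min_identity_pct=98.0))
        assert [h.subject_id for h in hits] == ["near"]


class TestEvalue:
    def test_linear_in_database_length(self):
        p = SearchParams()
        assert evalue(50, 100, 2000, p) == pytest.approx(2 * evalue(50, 100, 1000, p))

    def test_strictly_decreasing_in_score(self):
        p = SearchParams()
        assert evalue(60, 100, 1000, p) < evalue(50, 100, 1000, p)

    def test_closed_form_value(self):
        # direct evaluation of K*m*n*exp(-lambda*S) with the nt constants
        p = SearchParams()
        assert evalue(30, 100, 1000, p) == pytest.approx(
            0.46 * 100 * 1000 * math.exp(-1.28 * 30)
        )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, SearchParams())


class TestSoftMask:
    def test_polya_fully_masked_but_still_scored_through(self):
        """Seeds are never taken in the masked run, yet an alignment seeded
        outside extends across and scores it."""
        assert soft_mask("A" * 60) == [(0, 60)]
        rng = np.random.default_rng(10)
        flank = random_nt(rng, 60)
        seq = flank + "A" * 60
        rec = SeqRecord("a", seq)
        params = SearchParams(soft_mask=True)
        # pure poly-A queries share no unmasked seed -> no hit at all
        assert search(SeqRecord("pa", "A" * 60), [rec], params) == []
        # but the flanked sequence hits itself across the masked run
        (hit,) = [h for h in search(rec, [rec], params) if h.strand == "+"][:1]
        assert hit.q_end == 120 and hit.identity_pct == 100.0

    def test_random_uniform_sequence_unmasked(self):
        # seed picked by checking the windowed-entropy oracle directly
        rng = np.random.default_rng(12)
        seq = random_nt(rng, 60)
        from oracles import NEG  # noqa: F401  (namespace sanity)
        from hydraseq.aligner import shannon_entropy

        assert all(
            shannon_entropy(seq[i : i + 12]) >= 1.5 for i in range(len(seq) - 11)
        )
        assert soft_mask(seq) == []

    def test_dinucleotide_repeat_masked(self):
        assert soft_mask("AT" * 20) == [(0, 40)]


def test_database_reusable_across_queries():
    rng = np.random.default_rng(13)
    recs = [SeqRecord(f"r{i}", random_nt(rng, 100)) for i in range(4)]
    db = SequenceDatabase(recs, SearchParams())
    for rec in recs:
        assert search(rec, db)[0].subject_id == rec.id
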