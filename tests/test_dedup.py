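from __future__ import annotations

import numpy as np
import pytest

from hydraseq.core_io import ProteinRecord, SeqRecord
from hydraseq.dedup import (
    DedupParams,
    cluster_proteins,
    deduplicate,
    global_identity,
    redundancy_filter,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AAS), size=n))


def mutate_protein(rng, seq, k):
    chars = list(seq)
    for i in rng.choice(len(chars), size=k, replace=False):
        chars[i] = rng.choice([a for a in AAS if a != chars[i]])
    return "".join(chars)


class TestGlobalIdentity:
    def test_identical(self):
        rng = np.random.default_rng(60)
        p = random_protein(rng, 80)
        assert global_identity(p, p) == 100.0

    def test_four_substitutions_in_100(self):
        rng = np.random.default_rng(61)
        p = random_protein(rng, 100)
        q = mutate_protein(rng, p, 4)
        # gap penalty 20 makes the 4-mismatch gapless path optimal
        assert global_identity(p, q) == pytest.approx(96.0)

    def test_unrelated_proteins_far_below_threshold(self):
        rng = np.random.default_rng(62)
        a, b = random_protein(rng, 90), random_protein(rng, 90)
        assert global_identity(a, b) < 40.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "MKV")


class TestClustering:
    def test_copies_and_outlier(self):
        rng = np.random.default_rng(63)
        p = random_protein(rng, 70)
        prots = [ProteinRecord(f"c{i}", p) for i in range(3)]
        prots.append(ProteinRecord("x", random_protein(rng, 70)))
        clusters = cluster_proteins(prots)
        assert sorted(len(c) for c in clusters) == [1, 3]

    def test_truncated_fragment_forms_its_own_cluster(self):
        """A 80%-length fragment is locally identical but globally < 95%."""
        rng = np.random.default_rng(64)
        p = random_protein(rng, 100)
        full = ProteinRecord("full", p)
        frag = ProteinRecord("frag", p[:80])
        assert global_identity(full.seq, frag.seq) < 95.0
        assert len(cluster_proteins([full, frag])) == 2

    def test_partition_independent_of_input_order(self):
        rng = np.random.default_rng(65)
        prots = []
        for g in range(4):
            base = random_protein(rng, 60 + 5 * g)
            prots.append(ProteinRecord(f"g{g}a", base))
            prots.append(ProteinRecord(f"g{g}b", mutate_protein(rng, base, 1)))
        shuffled = [prots[i] for i in rng.permutation(len(prots))]
        part1 = {tuple(sorted(p.id for p in c)) for c in cluster_proteins(prots)}
        part2 = {tuple(sorted(p.id for p in c)) for c in cluster_proteins(shuffled)}
        assert part1 == part2


class TestCriteria:
    """Unit fixtures for the six discard criteria."""

    def test_exact_substring_discarded(self):
        rng = np.random.default_rng(66)
        big = random_protein(rng, 200)
        reps = [ProteinRecord("big", big), ProteinRecord("small", big[25:175])]
        kept, decisions = redundancy_filter(reps)
        assert [p.id for p in kept] == ["big"]
        assert any(d.failed_criterion == "discarded" and d.match_id == "small"
                   for d in decisions)

    def test_alignment_under_25_aa_ignored(self):
        rng = np.random.default_rng(67)
        shared = random_protein(rng, 24)
        a = ProteinRecord("a", shared + random_protein(rng, 80))
        b = ProteinRecord("b", random_protein(rng, 50) + shared)
        kept, decisions = redundancy_filter([a, b])
        assert {p.id for p in kept} == {"a", "b"}

    def test_gapped_alignment_keeps_splice_variants(self):
        rng = np.random.default_rng(68)
        exon1, exon2, exon3 = (random_protein(rng, 60) for _ in range(3))
        full = ProteinRecord("full", exon1 + exon2 + exon3)
        skip = ProteinRecord("skip", exon1 + exon3)
        kept, decisions = redundancy_filter([full, skip])
        assert {p.id for p in kept} == {"full", "skip"}
        assert any(d.failed_criterion in ("has_gaps", "span_low", "identity_low")
                   for d in decisions if d.match_id == "skip")

    def test_93_percent_span_kept(self):
        rng = np.random.default_rng(69)
        core = random_protein(rng, 280)
        match = ProteinRecord("m", core + random_protein(rng, 20))  # 280/300 = 93.3%
        query = ProteinRecord("q", random_protein(rng, 40) + core + random_protein(rng, 40))
        kept, decisions = redundancy_filter([query, match])
        assert {p.id for p in kept} == {"q", "m"}
        assert any(d.failed_criterion == "span_low" for d in decisions
                   if d.match_id == "m")

    def test_over_100_unmatched_residues_kept(self):
        rng = np.random.default_rng(70)
        core = random_protein(rng, 2200)
        # non-alignable homopolymeric tails so the local alignment stops at
        # the shared core and the >100 unmatched residues rule is what fires
        match = ProteinRecord("m", core + "P" * 110)
        query = ProteinRecord("q", core + "G" * 200)
        params = DedupParams(min_match_span=0.0)  # isolate criterion vi
        kept, decisions = redundancy_filter([query, match], params)
        assert {p.id for p in kept} == {"q", "m"}
        assert any(d.failed_criterion == "unmatched_high" for d in decisions
                   if d.match_id == "m")

    def test_equal_lengths_keep_both(self):
        rng = np.random.default_rng(71)
        p = random_protein(rng, 120)
        kept, _ = redundancy_filter([ProteinRecord("a", p), ProteinRecord("b", p)])
        assert {x.id for x in kept} == {"a", "b"}


class TestDeduplicate:
    def _transcripts(self, rng, n=6):
        from hydraseq.synthdata import SimConfig, generate_genome_and_transcripts

        cfg = SimConfig(seed=int(rng.integers(1 << 30)), n_genes=n,
                        genome_target_len=0, pseudogene_rate=0.0,
                        splice_variant_rate=0.0, rnaseq_only_frac=0.0,
                        predicted_only_frac=0.0,
                        paralog_family_sizes={1: 1.0})
        return generate_genome_and_transcripts(cfg).transcripts

    def test_unique_genes_unchanged(self):
        rng = np.random.default_rng(72)
        ts = self._transcripts(rng)
        kept, report = deduplicate(ts)
        assert {t.id for t in kept} == {t.id for t in ts}

    def test_corrupted_copies_collapse_to_full_transcript(self):
        from hydraseq.synthdata import corrupt_for_dedup

        rng = np.random.default_rng(73)
        ts = self._transcripts(rng)
        expanded, truth = corrupt_for_dedup(ts, seed=7)
        kept, report = deduplicate(expanded)
        assert {t.id for t in kept} == {t.id for t in ts}

    def test_short_orf_dropped_with_reason(self):
        rec = SeqRecord("short49", "ATG" + "GCT" * 48 + "TAA")  # 49-aa ORF
        kept, report = deduplicate([rec])
        assert kept == []
        row = report[report.id == "short49"].iloc[0]
        assert row.reason == "min_aa"

    def test_idempotence(self):
        from hydraseq.synthdata import corrupt_for_dedup

        rng = np.random.default_rng(74)
        ts = self._transcripts(rng, n=4)
        expanded, _ = corrupt_for_dedup(ts, seed=8)
        once, _ = deduplicate(expanded)
        twice, _ = deduplicate(once)
        assert {t.id for t in twice} == {t.id for t in once}
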