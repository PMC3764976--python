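from __future__ import annotations

import numpy as np
import pytest

from hydraseq.core_io import SeqRecord
from hydraseq.orftools import longest_orf
from hydraseq.synthdata import (
    IlluminaSim,
    Roche454Sim,
    SimConfig,
    corrupt_for_dedup,
    expand_redundancy,
    generate_genome_and_transcripts,
    generate_reads,
)


def _small_cfg(seed=11, **kw):
    defaults = dict(seed=seed, n_genes=12, genome_target_len=0,
                    illumina=IlluminaSim(n_reads=300),
                    fourfivefour=Roche454Sim(n_reads=150))
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenome:
    def test_same_seed_is_byte_identical(self):
        cfg = _small_cfg()
        s1 = generate_genome_and_transcripts(cfg)
        s2 = generate_genome_and_transcripts(cfg)
        assert [g.seq for g in s1.genome] == [g.seq for g in s2.genome]
        assert [t.seq for t in s1.transcripts] == [t.seq for t in s2.transcripts]
        assert s1.truth.equals(s2.truth)

    def test_zero_pseudogene_rate(self):
        sim = generate_genome_and_transcripts(_small_cfg(pseudogene_rate=0.0))
        assert not sim.truth.is_pseudogene.any()

    def test_realized_gc_tracks_configuration(self):
        """GC of a megabase-scale genome within one point of the target."""
        cfg = SimConfig(seed=3, n_genes=40, genome_target_len=1_000_000)
        sim = generate_genome_and_transcripts(cfg)
        seq = "".join(g.seq for g in sim.genome)
        assert len(seq) >= 1_000_000
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.30) < 0.01

    def test_every_sequence_has_exactly_one_truth_row(self):
        sim = generate_genome_and_transcripts(_small_cfg(pseudogene_rate=0.3))
        ids = [t.id for t in sim.transcripts] + [
            p.id for p in sim.predicted if p.id.replace("p_", "t_") not in
            {t.id for t in sim.transcripts}
        ]
        listed = set(sim.truth.seq_id)
        for t in sim.transcripts:
            assert t.id in listed
        assert sim.truth.seq_id.is_unique

    def test_withheld_sets_follow_truth_flags(self):
        sim = generate_genome_and_transcripts(_small_cfg(seed=21, n_genes=40))
        t_ids = {t.id for t in sim.transcripts}
        p_genes = {p.id[2:] for p in sim.predicted}
        for _, row in sim.truth.iterrows():
            if row.variant_type != "primary":
                continue
            assert (f"t_{row.gene_id}" in t_ids) == row.in_transcripts
            assert (row.gene_id in p_genes) == row.in_predicted

    def test_intact_gene_orfs_are_full_length(self):
        sim = generate_genome_and_transcripts(_small_cfg(seed=31))
        for t in sim.transcripts:
            row = sim.truth[sim.truth.seq_id == t.id].iloc[0]
            if row.variant_type == "primary":
                orf = longest_orf(t)
                assert orf.has_start and orf.has_stop
                assert orf.aa_len >= 100

    def test_pseudogene_orfs_are_short(self):
        sim = generate_genome_and_transcripts(_small_cfg(seed=41, pseudogene_rate=0.5))
        pseudo_ids = set(sim.truth[sim.truth.is_pseudogene].seq_id)
        assert pseudo_ids
        for t in sim.transcripts:
            if t.id in pseudo_ids:
                assert longest_orf(t).aa_len < 100


class TestReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = _small_cfg(
            illumina=IlluminaSim(n_reads=80, substitution_rate=0.0,
                                 adapter_readthrough_rate=0.0),
            fourfivefour=Roche454Sim(n_reads=40, homopolymer_indel_rate=0.0,
                                     leader_rate=0.0),
        )
        sim = generate_genome_and_transcripts(cfg)
        ilm, r454, audit = generate_reads(sim.transcripts, cfg)
        seqs = {t.id: t.seq for t in sim.transcripts}
        src = audit.set_index("read_id").source
        for read in ilm:
            assert read.seq[5:] in seqs[src[read.id]]
        for read in r454:
            assert read.seq in seqs[src[read.id]]

    def test_substitution_rate_within_binomial_bound(self):
        cfg = _small_cfg(
            illumina=IlluminaSim(n_reads=1500, substitution_rate=0.01,
                                 adapter_readthrough_rate=0.0))
        sim = generate_genome_and_transcripts(cfg)
        ilm, _, audit = generate_reads(sim.transcripts, cfg)
        seqs = {t.id: t.seq for t in sim.transcripts}
        info = audit.set_index("read_id")
        mismatches = bases = 0
        for read in ilm:
            row = info.loc[read.id]
            ref = seqs[row.source][row.start : row.start + 71]
            mismatches += sum(1 for a, b in zip(read.seq[5:], ref) if a != b)
            bases += 71
        p = 0.01
        sigma = (bases * p * (1 - p)) ** 0.5
        assert abs(mismatches - bases * p) < 3 * sigma

    def test_454_indels_confined_to_homopolymer_runs(self):
        cfg = _small_cfg(fourfivefour=Roche454Sim(n_reads=300,
                                                  homopolymer_indel_rate=0.2))
        sim = generate_genome_and_transcripts(cfg)
        _, r454, audit = generate_reads(sim.transcripts, cfg)
        indel_events = audit[audit.event.isin(["hp_ins", "hp_del"])]
        assert len(indel_events) > 0
        for _, ev in indel_events.iterrows():
            run_len = int(ev.detail.split(":")[-1])
            assert run_len >= 3

    def test_reads_deterministic_under_seed(self):
        cfg = _small_cfg()
        sim = generate_genome_and_transcripts(cfg)
        r1 = generate_reads(sim.transcripts, cfg)
        r2 = generate_reads(sim.transcripts, cfg)
        assert [x.seq for x in r1[0]] == [x.seq for x in r2[0]]
        assert [x.seq for x in r1[1]] == [x.seq for x in r2[1]]


class TestRedundancyExpansion:
    def test_factor_one_is_identity_up_to_renaming(self):
        rng = np.random.default_rng(110)
        ts = [SeqRecord(f"t{i}", "".join(rng.choice(list("ACGT"), 300))) for i in range(5)]
        out, truth = expand_redundancy(ts, 1, seed=1)
        assert [r.seq for r in out] == [t.seq for t in ts]

    def test_copies_stay_above_pairwise_identity_floor(self):
        """Audit: any two copies of one transcript differ at < 2% of sites."""
        rng = np.random.default_rng(111)
        ts = [SeqRecord(f"t{i}", "".join(rng.choice(list("ACGT"), 400))) for i in range(6)]
        out, truth = expand_redundancy(ts, 4, identity_floor=0.98, seed=2)
        groups = truth.groupby("origin").seq_id.apply(list)
        by_id = {r.id: r.seq for r in out}
        for ids in groups:
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    a, b = by_id[ids[i]], by_id[ids[j]]
                    diff = sum(1 for x, y in zip(a, b) if x != y)
                    assert diff / len(a) < 0.02

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            expand_redundancy([], 0)


class TestDedupCorruption:
    def test_corrupted_orfs_are_substrings_of_the_full_orf(self):
        cfg = _small_cfg(seed=51, paralog_family_sizes={1: 1.0},
                         splice_variant_rate=0.0, pseudogene_rate=0.0)
        sim = generate_genome_and_transcripts(cfg)
        expanded, truth = corrupt_for_dedup(sim.transcripts[:5], seed=3)
        full_peps = {t.id: longest_orf(t).peptide.seq for t in sim.transcripts[:5]}
        for _, row in truth.iterrows():
            if row.corruption == "none":
                continue
            rec = next(r for r in expanded if r.id == row.seq_id)
            pep = longest_orf(rec).peptide.seq
            trimmed = pep[: max(1, len(pep) - 25)]
            assert trimmed in full_peps[row.origin]
            assert len(pep) < len(full_peps[row.origin])
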