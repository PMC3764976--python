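"""Ground-truth synthetic data emulating every input the pipeline consumes.

The generator produces, under a single seed:

* a low-GC genome assembled from contigs carrying intron-containing genes
  (GT...AG intron ends), paralog families and intergenic spacers;
* the matching transcript set (exon concatenations with UTRs), a "predicted"
  transcriptome subset (some genes withheld to create RNAseq-only truth, and
  vice versa), optional splice variants, and pseudogenized gene copies
  reinserted into the genome;
* 76-nt barcoded Illumina-style reads with substitution errors and adapter
  read-through, and 454-style reads with homopolymer indels and trans-spliced
  leaders;
* contaminant sequences with their source databases;
* a redundancy expansion with a known redundancy factor.

Every emitted sequence has exactly one row in the accompanying truth table.
Randomness is fully seeded, with independent child streams per artifact so
that, e.g., changing read parameters does not perturb the genome.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import SeqRecord, revcomp
from .orftools import longest_orf

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class IlluminaSim:
    n_reads: int = 50_000
    read_len: int = 76
    barcode_len: int = 5
    substitution_rate: float = 0.005
    adapter_seq: str = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAGACCG"
    adapter_readthrough_rate: float = 0.05


@dataclass
class Roche454Sim:
    n_reads: int = 5_000
    mean_len: int = 295
    sd_len: int = 60
    min_len: int = 60
    homopolymer_indel_rate: float = 0.10  # per homopolymer run >= 3 nt
    leader_seq: str = "ACTCACTATTTAGGTAAG"  # trans-spliced leader, ends TAAG
    leader_rate: float = 0.25


@dataclass
class SimConfig:
    """Study conditions of the synthetic datasets (defaults at desk scale)."""

    seed: int = 0
    n_genes: int = 200
    paralog_family_sizes: dict = field(default_factory=lambda: {1: 0.80, 2: 0.15, 3: 0.05})
    paralog_divergence: float = 0.15  # substitution rate between paralogs
    splice_variant_rate: float = 0.10
    redundancy_factor: int = 1
    gc_content: float = 0.30  # low GC typical of the Hydra genome
    pseudogene_rate: float = 0.10
    stop_inductions_per_pseudogene: int = 3
    pseudogene_substitution_rate: float = 0.08
    rnaseq_only_frac: float = 0.15  # genes withheld from the predicted set
    predicted_only_frac: float = 0.10  # genes withheld from the transcript set
    contaminant_counts: dict = field(default_factory=dict)
    # gene model (invented desk-scale structure)
    cds_codons: tuple[int, int] = (110, 300)
    utr5_len: tuple[int, int] = (20, 100)
    utr3_len: tuple[int, int] = (30, 200)
    n_introns: tuple[int, int] = (0, 5)
    intron_len: tuple[int, int] = (60, 500)
    intergenic_len: tuple[int, int] = (200, 800)
    contig_target_len: int = 8_000
    genome_target_len: int = 1_000_000
    illumina: IlluminaSim = field(default_factory=IlluminaSim)
    fourfivefour: Roche454Sim = field(default_factory=Roche454Sim)

    def stream(self, name: str) -> np.random.Generator:
        """Independent deterministic random stream for one artifact."""
        tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence((self.seed, tag)))


@dataclass
class GenomeSim:
    """Output bundle of :func:`generate_genome_and_transcripts`."""

    genome: list[SeqRecord]
    transcripts: list[SeqRecord]
    predicted: list[SeqRecord]
    truth: pd.DataFrame


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=p))


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = _random_seq(rng, 3, gc)
        if codon not in _STOPS:
            return codon


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    body = "".join(_random_codon(rng, gc) for _ in range(n_codons - 2))
    return "ATG" + body + str(rng.choice(np.array(_STOPS)))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Random substitutions at ``rate`` per base (always to a different base)."""
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alt = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def _substitute_k(rng: np.random.Generator, seq: str, k: int) -> str:
    chars = list(seq)
    for i in rng.choice(len(chars), size=min(k, len(chars)), replace=False):
        alt = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def _repair_stops(rng: np.random.Generator, chars: list[str], cds_start: int, cds_end: int) -> None:
    """Re-randomize any in-frame stop codon inside a CDS (keeps paralog and
    variant coding stretches stop-free)."""
    for pos in range(cds_start, cds_end - 3, 3):
        if "".join(chars[pos : pos + 3]) in _STOPS:
            chars[pos : pos + 3] = list(_random_codon(rng, 0.5))


def _split_exons(rng: np.random.Generator, transcript: str, n_introns: int) -> list[str]:
    if n_introns == 0 or len(transcript) < (n_introns + 1) * 20:
        return [transcript]
    cuts = sorted(rng.choice(np.arange(10, len(transcript) - 10), size=n_introns, replace=False))
    exons, prev = [], 0
    for c in cuts:
        exons.append(transcript[prev:c])
        prev = int(c)
    exons.append(transcript[prev:])
    return exons


def _cap_orf(rng: np.random.Generator, seq: str, max_codons: int = 95) -> str:
    """Inject in-frame stop codons until no 6-frame stop-free stretch reaches
    ``max_codons`` codons (construction guarantee for pseudogene truth)."""
    rec = SeqRecord("tmp", seq)
    for _ in range(60):
        orf = longest_orf(rec)
        if orf.aa_len < max_codons:
            break
        mid = orf.aa_len // 2
        chars = list(rec.seq)
        if orf.strand == "+":
            start = orf.nt_start + 3 * mid
            chars[start : start + 3] = list(_STOPS[rng.integers(3)])
        else:
            stop = _STOPS[rng.integers(3)]
            # codon ``mid`` of the reading (reverse) strand on forward coords
            start = orf.nt_end - 3 * mid - 3
            chars[start : start + 3] = list(revcomp(stop))
        rec = SeqRecord("tmp", "".join(chars))
    return rec.seq


def _draw_family_sizes(rng: np.random.Generator, n_genes: int, dist: dict) -> list[int]:
    sizes = sorted(dist)
    probs = np.array([dist[s] for s in sizes], dtype=float)
    probs /= probs.sum()
    out, total = [], 0
    while total < n_genes:
        s = int(rng.choice(sizes, p=probs))
        s = min(s, n_genes - total)
        out.append(s)
        total += s
    return out


def generate_genome_and_transcripts(config: SimConfig) -> GenomeSim:
    """Genome contigs, transcripts, predicted subset and the truth table."""
    rng = config.stream("genome")
    gc = config.gc_content

    genes = []  # dicts: id, family, copy, transcript, exons, cds bounds
    fam_sizes = _draw_family_sizes(rng, config.n_genes, config.paralog_family_sizes)
    g_idx = 0
    for fam_idx, size in enumerate(fam_sizes):
        n_codons = int(rng.integers(*config.cds_codons))
        utr5 = _random_seq(rng, int(rng.integers(*config.utr5_len)), gc)
        utr3 = _random_seq(rng, int(rng.integers(*config.utr3_len)), gc)
        # an in-frame stop caps the 5' UTR so the gene's longest ORF is its CDS
        utr5 = utr5[:-3] + str(rng.choice(np.array(_STOPS)))
        base = utr5 + _random_cds(rng, n_codons, gc) + utr3
        cds_start, cds_end = len(utr5), len(utr5) + 3 * n_codons
        for copy in range(size):
            t = base
            if copy > 0:
                chars = list(_mutate(rng, base, config.paralog_divergence))
                chars[cds_start - 3 : cds_start + 3] = list(utr5[-3:] + "ATG")
                _repair_stops(rng, chars, cds_start, cds_end)
                t = "".join(chars)
            n_intr = int(rng.integers(config.n_introns[0], config.n_introns[1] + 1))
            genes.append(
                dict(id=f"g{g_idx:04d}", family=f"fam{fam_idx:03d}", copy=copy,
                     transcript=t, exons=_split_exons(rng, t, n_intr),
                     cds=(cds_start, cds_end))
            )
            g_idx += 1

    # withhold genes to create only-set truth (mutually exclusive draws)
    u = rng.random(len(genes))
    for gene, x in zip(genes, u):
        gene["rnaseq_only"] = x < config.rnaseq_only_frac
        gene["predicted_only"] = (
            config.rnaseq_only_frac <= x < config.rnaseq_only_frac + config.predicted_only_frac
        )

    # pseudogenes: diverged, stop-riddled copies of genes, later reinserted
    # verbatim into intergenic space and excluded from the predicted set
    n_pseudo = int(round(config.pseudogene_rate * len(genes)))
    pseudos = []
    for p_idx in range(n_pseudo):
        parent = genes[int(rng.integers(len(genes)))]
        seq = _mutate(rng, parent["transcript"], config.pseudogene_substitution_rate)
        chars = list(seq)
        cds_start, cds_end = parent["cds"]
        n_codons = (cds_end - cds_start) // 3
        for k in range(1, config.stop_inductions_per_pseudogene + 1):
            at = cds_start + 3 * int(k * n_codons / (config.stop_inductions_per_pseudogene + 1))
            chars[at : at + 3] = list(_STOPS[rng.integers(3)])
        seq = _cap_orf(rng, "".join(chars))
        pseudos.append(dict(id=f"pg{p_idx:03d}", parent=parent["id"], seq=seq))

    # assemble genome contigs: genes (with introns) and pseudogene inserts
    # separated by intergenic spacers
    inserts = []
    for gene in genes:
        gseq_parts = []
        for i, exon in enumerate(gene["exons"]):
            gseq_parts.append(exon)
            if i < len(gene["exons"]) - 1:
                ilen = int(rng.integers(*config.intron_len))
                gseq_parts.append("GT" + _random_seq(rng, ilen - 4, gc) + "AG")
        inserts.append("".join(gseq_parts))
    inserts.extend(p["seq"] for p in pseudos)
    order = rng.permutation(len(inserts))

    contigs, current, total = [], [], 0
    for idx in order:
        current.append(_random_seq(rng, int(rng.integers(*config.intergenic_len)), gc))
        current.append(inserts[idx])
        if sum(map(len, current)) >= config.contig_target_len:
            contigs.append("".join(current))
            current = []
    if current:
        contigs.append("".join(current))
    total = sum(map(len, contigs))
    while total < config.genome_target_len:
        pad = min(config.contig_target_len, config.genome_target_len - total)
        contigs.append(_random_seq(rng, pad, gc))
        total += pad
    genome = [SeqRecord(f"contig{i:04d}", s) for i, s in enumerate(contigs)]

    transcripts, predicted, rows = [], [], []

    def add_row(seq_id, gene_id, family, copy, variant, is_pseudo, in_t, in_p):
        rows.append(
            dict(seq_id=seq_id, gene_id=gene_id, family_id=family, copy_index=copy,
                 variant_type=variant, is_pseudogene=is_pseudo, is_contaminant=False,
                 in_transcripts=in_t, in_predicted=in_p,
                 rnaseq_only=in_t and not in_p, predicted_only=in_p and not in_t)
        )

    for gene in genes:
        rec = SeqRecord(f"t_{gene['id']}", gene["transcript"])
        in_t = not gene["predicted_only"]
        in_p = not gene["rnaseq_only"]
        if in_t:
            transcripts.append(rec)
        if in_p:
            predicted.append(SeqRecord(f"p_{gene['id']}", gene["transcript"]))
        add_row(rec.id, gene["id"], gene["family"], gene["copy"], "primary", False, in_t, in_p)
        if (
            in_t
            and len(gene["exons"]) >= 3
            and rng.random() < config.splice_variant_rate
        ):
            skip = int(rng.integers(1, len(gene["exons"]) - 1))
            var_seq = "".join(e for i, e in enumerate(gene["exons"]) if i != skip)
            var = SeqRecord(f"t_{gene['id']}_v1", var_seq)
            transcripts.append(var)
            add_row(var.id, gene["id"], gene["family"], gene["copy"], "splice", False, True, False)

    for p in pseudos:
        rec = SeqRecord(f"t_{p['id']}", p["seq"])
        transcripts.append(rec)
        add_row(rec.id, p["id"], p["parent"], 0, "pseudogene", True, True, False)

    truth = pd.DataFrame(rows)
    return GenomeSim(genome, transcripts, predicted, truth)


def _find_homopolymer_runs(seq: str, min_run: int = 3) -> list[tuple[int, int]]:
    runs, i = [], 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


def generate_reads(
    transcripts: list[SeqRecord], config: SimConfig
) -> tuple[list[SeqRecord], list[SeqRecord], pd.DataFrame]:
    """Illumina-style FASTQ reads and 454-style FASTA+QUAL reads.

    Returns (illumina_reads, fourfivefour_reads, audit) where the audit table
    logs each read's source and every induced 454 homopolymer indel.
    """
    ilm = config.illumina
    ff4 = config.fourfivefour
    audit_rows = []

    rng = config.stream("illumina")
    insert_len = ilm.read_len - ilm.barcode_len
    eligible = [t for t in transcripts if len(t.seq) >= insert_len]
    reads_ilm = []
    for r_idx in range(ilm.n_reads):
        t = eligible[int(rng.integers(len(eligible)))]
        if rng.random() < ilm.adapter_readthrough_rate:
            # fragment ends inside the read: 3' adapter is read through
            frag_len = int(rng.integers(max(10, insert_len // 3), insert_len))
            start = int(rng.integers(0, len(t.seq) - frag_len + 1))
            insert = (t.seq[start : start + frag_len] + ilm.adapter_seq)[:insert_len]
            readthrough = True
        else:
            start = int(rng.integers(0, len(t.seq) - insert_len + 1))
            insert = t.seq[start : start + insert_len]
            readthrough = False
        barcode = _random_seq(rng, ilm.barcode_len, 0.5)
        seq = _mutate(rng, barcode + insert, ilm.substitution_rate)
        qual = tuple(int(q) for q in rng.integers(30, 41, size=len(seq)))
        rid = f"ilm{r_idx:06d}"
        reads_ilm.append(SeqRecord(rid, seq, qual=qual))
        audit_rows.append(dict(read_id=rid, platform="illumina", source=t.id,
                               start=start, event="readthrough" if readthrough else "",
                               detail=""))

    rng = config.stream("454")
    reads_454 = []
    for r_idx in range(ff4.n_reads):
        t = transcripts[int(rng.integers(len(transcripts)))]
        length = int(np.clip(rng.normal(ff4.mean_len, ff4.sd_len), ff4.min_len, len(t.seq)))
        start = int(rng.integers(0, len(t.seq) - length + 1))
        sub = t.seq[start : start + length]
        rid = f"r454_{r_idx:05d}"
        # +-1 indels inside homopolymer runs, applied right-to-left so run
        # coordinates stay valid
        for a, b in reversed(_find_homopolymer_runs(sub)):
            if rng.random() < ff4.homopolymer_indel_rate:
                if rng.random() < 0.5:
                    sub = sub[:a] + sub[a] + sub[a:]
                    kind = "ins"
                else:
                    sub = sub[:a] + sub[a + 1 :]
                    kind = "del"
                audit_rows.append(dict(read_id=rid, platform="454", source=t.id,
                                       start=start, event=f"hp_{kind}",
                                       detail=f"run={sub[a] if a < len(sub) else ''}@{a}:{b - a}"))
        if rng.random() < ff4.leader_rate:
            sub = ff4.leader_seq + sub
            audit_rows.append(dict(read_id=rid, platform="454", source=t.id,
                                   start=start, event="leader", detail=""))
        qual = tuple(int(q) for q in rng.integers(20, 41, size=len(sub)))
        reads_454.append(SeqRecord(rid, sub, qual=qual))
        audit_rows.append(dict(read_id=rid, platform="454", source=t.id,
                               start=start, event="", detail=""))

    audit = pd.DataFrame(audit_rows, columns=["read_id", "platform", "source",
                                              "start", "event", "detail"])
    return reads_ilm, reads_454, audit


def expand_redundancy(
    transcripts: list[SeqRecord],
    factor: int,
    identity_floor: float = 0.98,
    seed: int = 0,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Duplicate each transcript to ``factor`` near-identical copies.

    Substitution counts per copy are bounded so that any two copies of the
    same transcript stay strictly above ``identity_floor`` pairwise identity
    (copy 0 is the unmutated original).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out, rows = [], []
    for t in transcripts:
        k_max = max(0, int((1.0 - identity_floor) / 2.0 * len(t.seq)) - 1)
        for j in range(factor):
            seq = t.seq if j == 0 else _substitute_k(rng, t.seq, int(rng.integers(0, k_max + 1)))
            rec = SeqRecord(f"{t.id}_r{j}", seq)
            out.append(rec)
            rows.append(dict(seq_id=rec.id, origin=t.id, copy_index=j))
    return out, pd.DataFrame(rows, columns=["seq_id", "origin", "copy_index"])


def corrupt_for_dedup(
    transcripts: list[SeqRecord], seed: int = 0
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Per transcript: the full copy, a truncated fragment and a frameshifted
    copy — the redundancy pattern the deduplication stage must collapse.

    The fragment keeps ~70% of the ORF codons.  The frameshifted copy loses
    one base mid-ORF; a stop codon is placed 8-15 codons downstream in the
    shifted frame, emulating the short nonsense peptide read through after a
    frameshift before translation terminates.
    """
    rng = np.random.default_rng(seed)
    out, rows = [], []
    for t in transcripts:
        orf = longest_orf(t)
        aa = orf.aa_len
        out.append(t)
        rows.append(dict(seq_id=t.id, origin=t.id, corruption="none"))
        # fragment: codons [a, a + ~0.7*aa) of the ORF
        frag_codons = max(55, int(0.7 * aa))
        a = int(rng.integers(0, max(1, aa - frag_codons)))
        lo = orf.nt_start + 3 * a
        frag = SeqRecord(f"{t.id}_frag", t.seq[lo : lo + 3 * frag_codons])
        out.append(frag)
        rows.append(dict(seq_id=frag.id, origin=t.id, corruption="fragment"))
        # frameshift in the distal ORF, nonsense tail capped by a forced stop;
        # the construction is validated (and redrawn) so the corrupted copy's
        # longest ORF really is a collapsible piece of the parent ORF — a
        # natural stop right after the shift can otherwise let a reverse-frame
        # stretch win instead
        full_pep = orf.peptide.seq
        fs = None
        for _ in range(8):
            c = max(55, int(rng.uniform(0.65, 0.9) * aa))
            pos = orf.nt_start + 3 * c
            chars = list(t.seq)
            del chars[pos]
            tail = int(rng.integers(8, 16))
            stop_at = pos + 3 * tail
            if stop_at + 3 <= len(chars):
                chars[stop_at : stop_at + 3] = list(_STOPS[rng.integers(3)])
            cand = SeqRecord(f"{t.id}_fs", "".join(chars))
            o = longest_orf(cand)
            pep = o.peptide.seq
            trimmed = pep[: max(1, len(pep) - 25)]
            if o.aa_len < 50 or (len(pep) < len(full_pep) and trimmed in full_pep):
                fs = cand
                break
        out.append(fs if fs is not None else cand)
        rows.append(dict(seq_id=f"{t.id}_fs", origin=t.id, corruption="frameshift"))
    return out, pd.DataFrame(rows, columns=["seq_id", "origin", "corruption"])


CONTAMINANT_GC = {"artemia": 0.42, "curvibacter": 0.62}


def generate_contaminants(
    config: SimConfig,
) -> tuple[dict[str, list[SeqRecord]], list[SeqRecord], pd.DataFrame]:
    """Contaminant databases plus spiked query sequences with truth labels.

    ``contaminant_counts`` maps label -> number of spiked queries; labels are
    database names or ``low_complexity``.  Spiked database contaminants are
    substrings of database sequences; low-complexity spikes are short-period
    repeats.
    """
    rng = config.stream("contaminants")
    dbs: dict[str, list[SeqRecord]] = {}
    for name, gc in CONTAMINANT_GC.items():
        dbs[name] = [
            SeqRecord(f"{name}_db{i:03d}", _random_seq(rng, int(rng.integers(500, 1500)), gc))
            for i in range(20)
        ]
    spiked, rows = [], []
    for label, count in config.contaminant_counts.items():
        for i in range(count):
            if label == "low_complexity":
                period = ["AT", "A", "CA", "TA"][int(rng.integers(4))]
                n = int(rng.integers(200, 400))
                seq = (period * n)[:n]
            else:
                src = dbs[label][int(rng.integers(len(dbs[label])))]
                n = int(rng.integers(150, min(600, len(src.seq))))
                start = int(rng.integers(0, len(src.seq) - n + 1))
                seq = src.seq[start : start + n]
            rec = SeqRecord(f"cont_{label}_{i:03d}", seq)
            spiked.append(rec)
            rows.append(dict(seq_id=rec.id, gene_id="", family_id="", copy_index=0,
                             variant_type="contaminant", is_pseudogene=False,
                             is_contaminant=True, contaminant_label=label))
    truth = pd.DataFrame(rows)
    return dbs, spiked, truth
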