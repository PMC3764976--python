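# Methods

`hydraseq` implements the bespoke computational stages of a hybrid
454/Illumina transcriptome study of *Hydra vulgaris*: read cleaning,
preparation of short-read contigs for co-assembly, ORF extraction, redundancy
removal, redundancy-index/gene-number estimation, dataset comparison
(only-sets, contaminant screening, genome support, pseudogene
classification), reciprocal-best-hit orthology and read-sampling saturation
analysis.  Everything is exercised on synthetic data with known ground
truth; external assemblers, mappers and annotation databases are out of
scope.

## Alignment engine

All similarity searches run through one internal seed-and-extend engine
(`hydraseq.aligner`):

* **Seeding.**  Exact shared words select candidate subject sequences and,
  for nucleotides, the strand (forward words against the subject and against
  its reverse complement).  Defaults: 11-nt words (megablast-like) for
  nucleotides; 4-mers over the Murphy 10-letter reduced alphabet for
  proteins.  No shared word means no hit — two unrelated sequences are never
  aligned.
* **Extension.**  Each candidate pair is extended by full optimal local
  dynamic programming with affine gaps (Biopython's `PairwiseAligner`, an
  exact Smith–Waterman implementation in C).  The reported top hit is
  therefore the exact DP optimum for the pair; the test suite verifies this
  against an independent pure-Python Smith–Waterman oracle.  Soft masking
  affects seeding only; masked stretches are scored normally during
  extension.
* **Scoring.**  Nucleotide: match +1, mismatch −2, gap open −5, gap
  extend −2.  `N` mismatches everything, including `N`.  Protein: BLOSUM62,
  gap open −11, gap extend −1, with `X`/`*` scored −4 against everything.
* **Identity.**  `identity_pct` = matches / alignment columns, gap columns
  counted as non-matches.  This is the identity of the best-scoring local
  alignment; for deeply diverged pairs (≲ 65% overall identity under the
  +1/−2 scheme) the optimum fragments into shorter, higher-identity blocks,
  so reported identities are those of the best block, as with BLAST HSPs.
* **E-values.**  Karlin–Altschul form `E = K·m·n·exp(−λS)` with constants
  fixed per scoring scheme (nucleotide λ = 1.28, K = 0.46; protein
  λ = 0.267, K = 0.041).  E-values gate hits; their absolute calibration is
  not load-bearing, only their ordering.
* **Low complexity.**  Windowed Shannon entropy below 1.5 bits over 12-nt
  windows (2.2 bits for proteins); flagged intervals are merged and excluded
  from seeding ("soft" masking).

## Read and contig cleaning

Illumina reads (76 nt, 5-nt barcode) pass through a fixed pipeline: barcode
strip → truncation at any exact match of an adapter's first 12 bases →
trimming of 3'-anchored inexact adapter overlaps (≥ 8 nt, ≤ 1 mismatch) →
removal of 3'-terminal homopolymer runs longer than 5 nt (the entire run) →
discard if > 90% of remaining bases have Phred ≤ 5 → discard if shorter
than 30 nt.  The quality and length filters are judged on the final trimmed
read, so quality is assessed on the bases actually retained.  Contig edges
lose trans-spliced-leader hallmarks: a TAAG wholly within the first 15 bp
removes the prefix through its last such occurrence; a CTTA wholly within
the last 15 bp removes the suffix from its first occurrence.

## Hybrid-assembly contig preparation

To bias an overlap assembler toward the more accurate short-read contigs,
each contig is duplicated (duplicate minus its first base, id suffixed
`_dup`), chopped to 1999-nt segments with 1899-nt overlaps when longer than
the cap, and given artificial qualities (Phred 40 internally, 10 over 25-bp
edges).  When the fixed 100-nt stepping leaves an uncovered tail, a final
clamped segment starting at `len − 1999` is appended, so every base is
covered and all segments have equal length; the final pair then overlaps by
more than 1899 nt.

## ORFs

An ORF is a stop-free codon stretch in one of six frames; a leading ATG is
not required ("full-length" ORFs additionally have start and stop).  The
longest ORF is selected by **nucleotide span with the terminating stop codon
included in the span** (but excluded from the peptide); ties break to the
'+' strand, then lower frame, then lower forward-strand start.  Ranking by
span rather than residue count makes a start-to-stop reading and a same-span
stop-less reading compare as equals, which keeps the selection
strand-symmetric.

## Redundancy removal

Longest ORFs are extracted; peptides < 50 aa are dropped; 25 C-terminal
residues are trimmed (the nonsense peptide translated beyond a frameshift is
short, so the trim suppresses that noise); trimmed peptides are clustered
greedily, longest-first, at ≥ 95% global identity (BLOSUM62 path with a
linear penalty of 20 per gap column; identity = matches / columns), keeping
the longest member per cluster.  Representatives are searched all-vs-all
(no masking) and a match is discarded only when **all** of: alignment
≥ 25 aa; query strictly longer; best-block identity > 95%; zero gap columns
(splice variants survive); alignment covering ≥ 95% of the match; ≤ 100
match residues outside the alignment ("unmatched" = residues outside the
aligned span).  Untruncated sequences are restored at the end — the C-trim
exists only inside clustering and filtering.

## Redundancy index and gene number

The redundancy index (RI) is the mean number of within-dataset hits per
query, computed on coding sequences (not full transcripts, which carry UTR,
vector and leader biases) with > 98%-identity, E ≤ 1e−30, soft-masked
search, capped at 250 alignments per query.  Self-hits count, so a fully
non-redundant set has RI = 1 and the gene-number estimate `n / RI` then
returns `n`.  The coding-length comparison takes, per reference sequence,
the best-scoring gap-free hit longer than 100 nt at ≥ 95% identity and
classifies the hit/reference length ratio into ≥ 100%, 75–99% and < 75%.

## Saturation analysis

A single seeded permutation of the reads is prefix-sliced into nested
subsamples (sampling without replacement), making detection counts monotone
in depth by construction.  Reads are mapped in a near-exact mode: the
aligner's word index proposes candidate references; each candidate is
verified by exact edit-distance alignment (edlib, both strands) accepting
≤ 5% errors per read; the best placement wins, ties to the
lexicographically first reference.  Under uniform synthetic coverage the
expected number of references detected at least once follows the classical
occupancy form `R·(1 − (1 − 1/R)^n)`, which the tests use as the analytic
oracle.

## Dataset comparison

Only-sets: a query is "only" when its best hit in the other dataset falls
below 95% identity (best-HSP identity, no coverage requirement, masking
off).  Contaminant screening is sequential: queries whose low-complexity
mask covers ≥ 80% of their length are labelled first; remaining queries are
assigned to the first database they hit and are not re-aligned to later
databases; the result is a partition.  Genome support requires a best
genomic hit above 75% identity.  A pseudogene candidate has an ORF < 100 aa
that spans < 95% of its transcript, a perfect genome match, and < 95%
identity to every predicted transcript.  A "perfect match" (100% identity,
zero gaps, full transcript length) holds exactly when the transcript occurs
verbatim in a contig on either strand, so it is implemented as an exact
substring test; spliced transcripts therefore never match perfectly, which
is what makes the screen specific — and also why spliced pseudogenes escape
it.

## RBH orthology

A pair is reported when each protein is the other's unique best-scoring hit
(soft-masked BLOSUM62 search, E ≤ 1e−8 both directions).  A tie for best
score disqualifies the query — conservative, and it keeps the output a
partial matching.  Subset views (e.g. orthologs among an only-set) filter
pairs computed on whole proteomes rather than re-searching the subset.

## Synthetic data

The generator emulates the study's inputs at desk scale with full
determinism (independent child streams per artifact, so changing read
parameters does not perturb the genome):

* **Genome & genes.**  Low-GC genome (30% GC, matching *Hydra*); genes with
  110–300 codon CDS, 20–100 nt 5' UTR (capped by an in-frame stop just
  before the ATG, as real UTRs almost always are, so the longest ORF of an
  intact gene is its CDS), 30–200 nt 3' UTR, 0–5 introns of 60–500 nt with
  GT…AG ends; paralog families (default 80/15/5% of sizes 1/2/3) at ~85%
  identity with stop-repaired CDS; intergenic spacers of 200–800 nt packed
  into ~8-kb contigs, padded with intergenic contigs to a 1-Mb default.
* **Only-set truth.**  A configurable fraction of genes is withheld from the
  predicted set (RNAseq-only truth) or from the transcript set
  (predicted-only truth); splice variants (one skipped internal exon) join
  the transcript set only.
* **Pseudogenes.**  Diverged copies of parent mRNAs (8% substitutions, so
  < 95% identity to the parent) with forced in-frame stops, inserted
  verbatim into intergenic space and excluded from the predicted set.  A
  repair loop injects additional stops until no 6-frame stop-free stretch
  reaches 95 codons; without it, stop-free runs spilling into the random 3'
  UTR would exceed 100 aa often enough to blur the ground truth.
* **Reads.**  Illumina: 76 nt = 5-nt barcode + insert, substitution errors
  (default 0.5%), occasional 3'-adapter read-through.  454: ~N(295, 60) nt
  lengths, ±1 indels confined to homopolymer runs ≥ 3 nt, trans-spliced
  leader (ending TAAG) prepended at a configurable rate.  An audit table
  logs every event for the property tests.
* **Redundancy expansion.**  Each transcript is copied `factor` times;
  substitution counts are bounded by `⌊(1 − floor)/2·L⌋ − 1` so any *pair*
  of copies stays strictly above the identity floor (98% by default) — the
  bound is on pairwise, not per-copy, divergence, which is what the RI
  search thresholds act on.
* **Dedup corruption.**  Per transcript: the full copy, a fragment keeping
  ~70% of the ORF codons, and a frameshifted copy (one deleted base in the
  distal ORF, nonsense tail capped by a stop 8–15 codons downstream,
  mirroring the short read-through peptide after a frameshift).  The
  construction is validated and redrawn if a reverse-frame stretch would
  outrank the truncated forward ORF, so the corrupted copies are collapsible
  by the stated criteria by construction.

What the generator does **not** emulate: realistic quality-score profiles,
coverage biases, chimeric reads, alternative splicing beyond single-exon
skipping, allelic variation, and spliced (processed-with-introns)
pseudogenes.  Passing tests therefore demonstrate correctness of the
implemented rules on data satisfying their assumptions, not robustness to
every artifact of real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the simulation-backed analyses
at desk scale — 20–60 genes, genomes of 50–200 kb (1 Mb only for the GC
property), hundreds to a few thousand reads, 20 replicates for stochastic
checks — sizes chosen so the whole suite completes in a few minutes while
keeping every statistical check well-powered (3σ bands on binomial/occupancy
quantities).  Thresholds follow the defaults above and are exposed as
function parameters and CLI flags.  Degenerate inputs are handled
explicitly: empty datasets raise; a transcript whose every frame is
wall-to-wall stops yields a zero-length ORF; equal-length proteins never
discard each other; tied best scores form no RBH pair.

## Known limitations

* The aligner returns one best hit per subject and strand — no multi-HSP
  chaining; translated (blastx-style) search is composed from ORF extraction
  plus protein search rather than built in.
* E-value constants are fixed per scheme, not estimated from the scoring
  matrix; absolute E-values are approximate.
* Greedy longest-first clustering approximates the reference clustering
  tool's behaviour, not bit-for-bit.
* Best-HSP identity can exceed whole-sequence identity for diverged pairs
  (see Alignment engine); the 75% genome-support rule inherits this
  behaviour from its BLAST-based ancestor.
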