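# Methods

This note documents the models and procedures implemented in `excluseq`,
the defaults and why they were chosen, what the synthetic data does and
does not emulate, and the numerical choices that affect results.

## The discovery procedure

The pipeline finds transcripts expressed exclusively in one condition
("carrier") of a two-condition RNA-seq design, with no reference sequence
for their source (a supernumerary B chromosome). Four stages:

**Assembly.** Each condition's reads are assembled independently into a
canonical de Bruijn graph: every k-mer of every read (k odd) is stored
once for itself and its reverse complement with a multiplicity count;
k-mers containing N are skipped. Contigs are *unitigs* — maximal
non-branching paths — extracted after tip removal (dead-end paths no
longer than 2k with mean multiplicity below `min_coverage`). This is a
deliberately minimal assembler: no bubble popping, no scaffolding, no
isoform resolution. At desk scale with error-free or low-error reads,
unitigs reconstruct planted transcripts exactly; that simplification is
the package's declared delta from a production transcriptome assembler.
Assembly runs at several k and unions the results, dropping any contig
that is identical to or an exact substring (either strand) of a longer
retained contig. Defaults: k ∈ {21, 31, 41} for 100-bp simulated reads
(a 51–93 range suits deeper real 100-bp libraries and is configurable),
`min_coverage` 3, `min_length` 200, tip length 2k — standard
small-assembler heuristics, all exposed.

**Subtraction.** A carrier contig survives iff it has no local-alignment
hit against the wild-type contig set at E ≤ 0.1. The aligner is
seed-and-extend: exact seed words are grouped per (subject, diagonal),
extended ungapped first (the exact maximum-subarray score on the
diagonal), and the best regions get a gapped Gotoh extension. Pairs small
enough for a full dynamic-programming matrix (≤ 3·10⁵ cells) are aligned
exactly, so reported scores on desk-scale instances equal the
Smith–Waterman optimum; larger pairs use a ±50 window around the seed
diagonal. E-values are Karlin–Altschul, E = K·m·n·e^(−λS), with published
*ungapped* parameters (+1/−2: λ=1.28, K=0.46; BLOSUM62: λ=0.3176,
K=0.134) applied to gapped scores — an approximation that is conservative
(it overestimates E) and adequate at the permissive cutoffs used (0.1 for
subtraction, 0.01 for protein homology). Exact gapped recalibration is
out of scope.

The nucleotide seed word is 28 nt (megablast-like). This is a substantive
choice, not a tuning knob: with an 11-nt word and correctly calibrated
e-values, a cutoff of E ≤ 0.1 *by definition* admits ~0.1 chance
alignments per query-strand, so a handful of genuinely exclusive contigs
per run would be wrongly subtracted by ~19-bp chance alignments. A 28-nt
exact seed makes chance seeding between unrelated sequences essentially
impossible (probability ~ m·n/4²⁸) while leaving true homologs — which
share long exact runs — fully visible. The word size is configurable; the
aligner-oracle tests use word 11 to exercise seeding-sensitive paths.

**Verification.** Both read sets are mapped to the candidate contigs with
exact-match semantics and the two multiplicity caps of the `-k 50 -m 50`
contract: a read's placements are all exact full-length occurrences on
either strand across all features; more than 50 placements discards the
read entirely (it counts nowhere and leaves the mapped total); otherwise
the read increments each distinct feature among its first 50 placements
(ordered by feature id, offset, strand) once. These semantics are part of
the contract, not an implementation detail — the exclusivity call relies
on them. Abundance: RPM = count/total_mapped × 10⁶ and FPKM =
count/((length/10³)·(total_mapped/10⁶)), with the denominator pinned to
*reads mapped to the candidate index* (a config-visible choice; the
library-total alternative differs only by a constant factor within one
run). A read mapping multiple times within one feature counts once, so
counts conserve: mapped + unmapped + discarded = total. Mates are mapped
as singletons; FPKM "fragments" are approximated by read counts.
Mismatch tolerance (> 0) is Hamming-only seed-and-verify; indels are
never allowed, matching the exact-match model.

**Exclusion cascade.** Filters apply in a fixed order so each exclusion
names its first failing test: opposite-condition reads (any WT read
excludes, threshold 0, exposed because one-WT-read borderline cases are a
recognised grey zone), then minimum carrier reads (50), then minimum RPM
(10). The order cannot change the final exclusive set, only the audit
labels. The reciprocal check mirrors the cascade with roles swapped:
a WT contig is reported only if it has no carrier-assembly homolog, *and*
no more than the opposite-condition read allowance of carrier reads, *and*
is above background (strictly more than 10 WT reads or 2 RPM). The
opposite-read condition matters in practice: at desk-scale depth,
multinomial sampling noise lets a weakly expressed shared transcript
assemble partially in one condition only; its abundant reads in the other
condition are exactly what identifies it as shared.

## Annotation-side analyses

**ORFs.** All six frames are scanned; an ORF runs from the first ATG
after each stop to the next stop (nested ATGs are not re-reported), with
open-ended ORFs at the sequence end included by default. Coordinates are
reported on the forward strand of the input; `length_aa` excludes the
stop.

**Coding potential** is a rule cascade applied to a contig with its
two-sample quantification: translated homology at E < 0.01 →
`coding_homology`; else longest ORF strictly greater than 200 aa →
`coding_orf`; else length ≥ 200 bp and FPKM ≥ 10 in at least one sample →
`noncoding_candidate` (the long-noncoding class); else
`below_expression`. This replaces a likelihood-based frame scorer with
the literal published thresholds; the cascade's boundaries are tested at
199/200/201.

**NTR calling** compares genome-placed transcript models against the
annotation at exon level (strand-aware by default; both an unstranded
switch and a gene-span overlap option exist, since both conventions occur
in practice): identical exon chain → `known`; ≥ 1 bp exon overlap but a
different chain → `new_isoform`; no overlap → `ntr`. The novel-bp total
is the length of the union of ntr exon intervals (no double counting).
Genome placement of real assembled contigs (spliced alignment) is out of
scope; the synthetic generator emits placed models directly.

**Junction comparison** is set semantics on (chrom, strand, donor end,
acceptor start) tuples: confirmed = assembled ∩ annotated, novel =
assembled \ annotated.

**Two-condition comparison.** Pearson r is computed on log₂(FPKM+1)
(the pseudocount avoids −∞ at zero counts; the transform for the
published correlation is not otherwise constrained) over features with a
nonzero count in at least one sample. Each feature gets a two-sided exact
conditional test (Fisher) of count_a/total_a vs count_b/total_b with
Benjamini–Hochberg correction; direction is assigned at q < α. The totals
are *effective library sizes* from a swap-symmetric median-log-ratio
normalisation (skipped below 10 co-expressed features): under multinomial
read sampling, changing any feature's abundance shifts every other
feature's raw proportion (compositional distortion), and raw-total tests
then flag abundant null features. The normalisation is symmetric in the
two samples, so exchanging them transposes every table and preserves
every p-value exactly while flipping directions. This exact-test stand-in
replaces a dispersion-modelling DE engine: with one library per condition
there are no replicates to estimate biological dispersion from, so its
p-values describe sampling variability only — adequate for the simulated
design, anticonservative for real biology.

## The synthetic data

`SimulationConfig` defaults define the study regime the pipeline targets:
two 500-kb chromosomes plus a 100-kb B chromosome present only in the
carrier; 200 shared transcripts (single-exon by default; a 2–4-exon
option exists for junction/NTR testing) of 500–1500 bp placed without
overlap, 20 of them differentially expressed at 5-fold (half up, half
down); 25 novel loci transcribed but absent from the emitted GTF; 9
exclusive transcripts on the B chromosome; 10⁵ read pairs per condition
(equal depth by default, per-condition depth exposed), 100-bp reads,
fragment length 250 ± 30, substitution-only errors at a default rate of
0 (the verification mapper is exact-match, so indel or high-error reads
would only inflate the unmapped fraction).

Expression levels are log-normal (σ = 1), giving the wide dynamic range
characteristic of RNA-seq; shared-transcript levels are identical across
conditions except for the designated DE genes, which is what makes the
near-unity cross-condition correlation an emergent property (observed
r ≈ 0.99 on no-DE simulations). Exclusive transcripts are drawn from the
same distribution but boosted to a minimum expected 200 fragment pairs:
the discovery procedure targets *abundantly expressed* exclusive
transcripts (the reported ones span 10–1163 RPM, i.e. hundreds to
thousands of reads at real depth), and an unconstrained draw would
occasionally plant an exclusive below its own 50-read filter.

Fragments are multinomial over expression × length with uniform start
positions, mate 2 reverse-complemented. A consequence worth knowing: the
first and last k−1 bases of a transcript are covered only by fragments
starting exactly at the boundary, so random placement at moderate depth
leaves contigs a few bases short of the transcript ends. Tests of *exact*
reconstruction therefore use `tile_reads` (deterministic stride-3 tiling,
~33× with the final window forced), while end-to-end recovery tests match
contigs to transcripts by containment. The "repeat-free" option used by
reconstruction tests resamples the genome until no canonical k-mer of the
configured size repeats in the transcriptome *and* none is its own
reverse complement — an even-length palindromic window behaves like a
repeat in a bidirected graph and splits an otherwise clean unitig.

What the generator does not emulate: empirical quality-score profiles,
PCR duplicates, indel errors, positional coverage bias, polyA tails,
paralog families, or genomic repeats. Passing tests therefore demonstrate
the pipeline's logic — subtraction, the mapping contract, the cascade,
the statistics — not robustness to those real-data artifacts.

## Determinism and numerics

All randomness flows through seeded PCG64 generators with fixed
derivation paths, so identical configs give byte-identical genomes,
reads, assemblies and reports; graph traversal enumerates unitigs from
the lexicographically smallest canonical k-mer, contigs are
canonical-strand min(seq, rc), multi-k output sorts by (length desc, id),
hits sort by (e-value, −score, subject, position), and equal-score
alignments trace back diagonal-first. K-mers are packed two bits per base
into one 64-bit limb (k ≤ 32), two limbs (k ≤ 63), or arbitrary-precision
integers beyond that (functional, not fast). Alignment scores are exact
integers; the only floating-point quantities are e-values, abundances and
p-values.

## Problem sizes

The test suite and acceptance script run the default design (10⁵ read
pairs per condition, ~234 transcripts) seed-swept ×20 for recovery
properties, 2,000 features × 20 seeds for test calibration, 500 random
sequences for the ORF oracle, and 200 random pairs for the alignment
oracle — sizes chosen so planted effects are unambiguous while a full run
of everything stays within a coffee break on one CPU.
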