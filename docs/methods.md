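# Methods

This note documents the models, parameter choices and numerical decisions
behind `seedmir`, and what the synthetic-data generator does and does not
emulate.

## Pipeline model

The pipeline targets genome-free plant small-RNA studies: two (or more)
sequencing libraries of 18–25 nt reads, and a set of transcript contigs
assembled from mRNA-seq that serves as the search space for precursors and
targets. Stages run in a fixed order — preprocess, ncRNA/conserved
annotation, precursor discovery, quantification, differential abundance,
target prediction, report — and every stage writes plain-text artifacts
(TSV/FASTA/GFF3) from which each reported number can be recomputed.

## Preprocessing

- **Quality rule.** "Low quality" is interpreted as *mean* Phred below the
  threshold (default 13) over the read; a `quality_rule="min"` switch uses
  the minimum base quality instead. The mean rule is the default because a
  single poor 3' cycle should not discard an otherwise clean read whose
  insert is intact after trimming.
- **Adapter trimming** is exact-match only: the longest read suffix equal
  to a prefix of the 3' adapter (≥ 8 nt), or a full-adapter occurrence
  anywhere, is removed; a symmetric rule applies to an optional 5' adapter.
  Exactness keeps the operation deterministic and auditable; reads whose
  adapter is error-containing simply fail the length window downstream.
- **Order**: quality → trim → drop-N → length window. The cascade is a
  partition: every input read is counted exactly once as removed-low-quality,
  removed-N, too-short, too-long or retained, and the pipeline manifest
  asserts this conservation per library.
- **Rounding dialects.** Printed summary tables use half-up rounding, one
  decimal for length tallies and two decimals for class tallies, matching
  the conventions of published summary tables in this literature.

## Annotation

ncRNA exclusion uses zero-mismatch full-length substring containment on
both strands of the class references — the conservative reading of
"exact-match short-read mapping" that needs no aligner parameters. Class
precedence is miRNA > rRNA > tRNA > snRNA > snoRNA > mtRNA > cpRNA, so a
tag identical to a known mature miRNA is never swallowed by the exclusion
set; precedence is configurable. Conserved matching requires full-length
identity (zero mismatches), so a tag one substitution away from every
reference stays unassigned. Family names are parsed from reference ids by
stripping the species prefix, letter/paralog suffixes and arm labels;
MIR156/157, MIR165/166 and MIR170/171 are merged.

## Precursor discovery

- **Anchoring.** Hits chain into a block when their intervals overlap or
  their starts differ by ≤ 3 nt (transitively); the gap is exposed as
  `chain_gap`. A contig-strand passes with 1–2 blocks, all hits on one
  strand, and ≥ 11 summed reads ("more than 10"), read as a per-contig
  total.
- **Window.** Contigs ≤ 300 nt are folded whole; otherwise the window spans
  the blocks ± 20 nt. Both modes exist because the right choice depends on
  contig length relative to the precursor.
- **Folding** wraps the ViennaRNA MFE folder; tests assert structural
  invariants (balanced brackets, arm pairing of constructed hairpins), not
  engine-specific energies.
- **Validation.** |MFEI| ≥ 0.85; the dominant product must have ≥ 75 % of
  its bases paired to positions outside its own footprint (the opposite
  arm) and ≤ 3 bases inside the terminal loop. The 75 %/3-base pair
  operationalize "almost complementary, with few mismatches" and are
  configurable. The plausibility band 40–100 kcal/mol on |MFE| is a warning
  flag, not a filter: genuine precursors fall outside it in both
  directions.
- **Partials.** A candidate that fails hairpin validation is kept with
  `status=partial` only when its dominant mature is identical to a known
  Bna mature — the conservative analogue of keeping partial precursors on
  the strength of known identity.
- **Tie-break.** Equal-count tags on an arm resolve to the
  lexicographically smallest sequence, so results are order-independent.
- **Arms.** The terminal loop is the most deeply nested hairpin loop of the
  structure; a product belongs to the arm holding its midpoint. 5p/3p labels
  follow position relative to that loop.

## Differential abundance

The intended study design has one library per condition, so tagwise
dispersion estimation is impossible; dispersion is a configuration
parameter (default 0.1, roughly a BCV of 0.32; 0 gives the Poisson /
exact-binomial limit). The NB exact test conditions on the pairwise total
x+y, splitting it with probabilities proportional to the TMM-adjusted
effective library sizes, and sums the probabilities of all splits no more
likely than the observed one (edgeR's "smallp" rejection region; an
independent edgeR run is used as a test oracle). The Audic–Claverie
posterior is evaluated through its negative-binomial identity
p(y|x) = NB(y; x+1, N1/(N1+N2)); the reported one-sided p is the smaller
tail and the two-sided p doubles it, capped at 1. Note the AC test is not
exactly symmetric under swapping (x, N1) with (y, N2) — conditioning on x
and on y sums different index sets — though the two directions agree
closely for moderate counts. p-values are clamped to [1e-300, 1] so the
0 < p ≤ 1 contract survives floating-point underflow at extreme splits.

TMM uses 30 % two-sided trimming on M and 5 % on A, inverse-variance
weights, rows with zeros excluded, and factors rescaled to geometric mean
1. The reference library is the one whose 75th percentile of nonzero
size-scaled counts is closest to the mean of those percentiles. Fold change
is the ratio of TMM-scaled counts-per-million with a pseudocount of 1
(scale-invariant and defined at zero counts). A locus is called only when
both tests give p ≤ 0.001 (boundary inclusive); |fold| > 2 adds a highlight
flag, mirroring how such studies report "differential and > 2-fold".

## Target prediction

The expectation score is the classical plant-target penalty scheme:
Watson–Crick 0, G:U wobble 0.5, mismatch 1, gap/bulge 2, all doubled at
miRNA positions 2–13 counted from the 5' end; at most one gap per duplex.
A gap sitting between miRNA positions b and b+1 takes the core multiplier
of position b (clamped to [1, m]). The scanner scores every window of
length m−1, m and m+1 on both strands and keeps E ≤ 4; the cutoff follows
the score, not the mismatch count (a core mismatch costs 2, so "4" is not
"four mismatches"). All penalties are configurable.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Hairpins**: 21-nt arms (18–25 supported), the 3' arm the reverse
  complement of the 5' arm with exactly `star_mismatches` (default 2)
  pair-breaking substitutions placed away from the stem ends; loops of
  8–15 nt drawn from {A, C} so they stay unstructured; arm GC within ±0.1
  of the target (default 0.45). A 15-nt paired lower-stem extension flanks
  the mature:star duplex — real pre-miRNAs have stems longer than the
  mature duplex, and without it hairpin MFEI is unrealistically weak
  (~0.7 instead of the ~1.0 typical of plant precursors).
- **Contigs**: each precursor is embedded with 130–250 nt random flanks
  (decoys are pure random sequence), placing simulated contigs in the size
  range of short assembled transcripts while guaranteeing ≥ 20 nt flanks.
- **Reads**: per-locus mature counts are Poisson around
  abundance × fold-change (negative binomial behind a dispersion parameter);
  stars at 10 % of the mature rate; isomiRs at rate 0.2 with uniform ±1/±2
  offsets on a random end; ncRNA contaminants (default 10 %) are substrings
  of the generated class references; background filler reads pad each
  library to exactly `total_reads`. Insert lengths of contaminant and
  background reads peak at 24 nt against the 21-nt matures, reproducing the
  21/24 bimodal length profile of plant seed libraries. Each read carries
  the full 3' adapter and constant Phred 30 qualities, with configurable
  low-quality (Phred 2) and N-containing fractions to exercise the
  cleaning cascade. Mature arms start with U with probability 0.8.
- **Defaults**: 24 precursors (3 known-Bna, 3 known-plant, rest novel),
  30 decoy contigs, two libraries of 30,000 reads, 300 expected reads per
  locus. Per-locus abundance is uniform by default — no abundance
  distribution is implied by the modelled study type, so the simplest
  choice is used and documented rather than inferred.

What it does **not** emulate: Illumina error profiles, 5' adapters by
default, multi-branched precursors, genomic (vs transcript) context,
degradation products with positional structure, or realistic abundance
skew. Passing tests therefore demonstrate correctness of the pipeline's
logic and statistics under the stated generative assumptions, not
performance on real libraries.

## Determinism

All randomness flows through numpy Generators seeded from a single integer;
fixed seed ⇒ byte-identical FASTQ/FASTA/TSV outputs and a byte-identical
rerun of the whole pipeline (the manifest contains no timestamps). Problem
sizes used by the test suite and the acceptance script (reduced read counts
for unit fixtures, 2 kb contigs for the scanner cross-check, 2000 loci for
the null calibration, 20 replicates for power) were chosen to make the
checks statistically meaningful while keeping a full run fast on one CPU.

## Known limitations

- With a single library per condition the dispersion default is a judgment
  call, not an estimate; DE calls at dispersion 0 are anti-conservative for
  overdispersed data.
- Exact-match mapping means a single sequencing error removes a read from
  every downstream tally; there is no mismatch-tolerant mode.
- The identification summary counts novel families as distinct dominant
  mature sequences, which over-counts if two novel precursors shed
  near-identical (but not identical) matures.
- Target scanning enumerates every window with at most one gap; it is exact
  but quadratic-ish, sized for transcript contigs rather than chromosomes.
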