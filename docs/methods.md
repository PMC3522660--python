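# Methods

This note documents the models, parameter choices and numerical conventions
behind mitopool, and what the synthetic benchmarks do and do not demonstrate.

## The screening model

Tag-free multiplexing rests on one requirement: for every pair of pooled
mitogenomes, no stretch the length of a sequencing read may be (near-)
identical, otherwise reads from that stretch cannot be attributed and
assembly may merge the genomes. Two measurements operationalise this:

- **Folmer COI proxy.** The p-distance over positions 50–700 of the COI gene
  (1-based inclusive, 651 bp). The bounds are read as 1-based inclusive
  because that yields the conventional ~650 bp animal barcode length. When
  COI is shorter than 700 bp the available overlap is used with a warning.
- **Sliding-window profiles.** p-distances in windows of 150 bp (step 15)
  or 450 bp (step 45) along a pairwise alignment. 450/150 bp correspond to
  long- and short-read desktop platforms; longer windows bridge conserved
  regions, so they tolerate less divergent pairs.

p-distances use **pairwise deletion**: only columns where both rows are in
{A,C,G,T} are compared; gaps and N are excluded but reported through the
per-window `comparable` count. A window is flagged `low_info` when fewer than
`min_comparable_frac` (default 0.5) of its columns are comparable. This
repairs a visualization trap: when one genome carries a long deletion, a
naive profile reports 0% divergence there although nothing was compared. The
0.5 default is a repair threshold of our choosing, configurable, not an
estimate of anything.

**Pooling policy** (defaults): compatible iff COI proxy ≥ 0.15, or — when a
450 bp profile exists (`windows_preferred`) — iff the minimum informative
window divergence ≥ 0.05. Pairs with no usable evidence are incompatible
("insufficient data"): the conservative choice, since pooling an unscreened
pair risks the whole run. The largest pool is a maximum clique (exact
enumeration ≤ 25 specimens via maximal-clique listing; seeded greedy + swap
above, with ties broken toward the lexicographically smallest member list).
Partitioning a sample set into runs is graph colouring of the
incompatibility graph (DSATUR heuristic, with the largest mutually
incompatible set reported as a lower bound; on random 8-specimen instances
the heuristic matches the exact chromatic number ≥ 90% of the time and never
exceeds it by more than one).

## Alignment

Full-genome pairs are aligned by **anchored alignment**: unique 15-mers
shared by both sequences are chained (longest strictly-collinear chain);
inter-anchor gaps ≤ 5,000 columns are closed with affine-gap global
Needleman–Wunsch (match +1, mismatch −1, gap open −4 for the first gapped
column, −1 per further column — Biopython's `PairwiseAligner` semantics).
Fewer than 3 collinear anchors raises an error instructing the user to
supply an external alignment; this deliberately refuses pairs too divergent
for reliable anchoring rather than returning a poor alignment. On ≤ 2 kb
sequences the anchored result is score-identical to unanchored NW in the
suite's oracle checks. Folmer fragments (651 bp) are aligned unanchored.

## Run capacity

`genomes/run = round_half_up(T·f / (G·c))` and
`cost/genome = round_half_up(run_cost / (T·f/(G·c)), 2 decimals)` with
defaults G = 17,000 bp and f = 0.5 (an enrichment yielding 50% mitochondrial
DNA at equimolarity). Half-up rounding on both quantities, with the cost
taken from the *unrounded* quotient, is the unique convention consistent
with the platform table shipped in `PLATFORM_PRESETS` (e.g. 20.59 → 21
genomes; 425/58.82 = 7.225 → 7.23).

## Read simulation

The error model follows the wgsim family parameterisation: per-base read
substitution rate 0.02; per-site haplotype mutation rate 0.001 applied once
per genome per run (9/10 substitutions uniform over the three alternatives,
1/10 indels, insertion/deletion equally likely, geometric length with
extension probability 0.3, mean 1/0.7 ≈ 1.43); contamination reads of
uniform random DNA with probability 0.05 per read. Reads are drawn uniformly
on the circle; origin-spanning reads are generated and flagged. Truth
records carry origin, 0-based start on the mutated haplotype, strand,
per-read error counts and the wrap flag, so calibration is measured against
truth rather than trusted.

Choices the model parameterisation leaves open:

- **Contamination is additive**: the target genome-derived read count
  `ceil(c·L/ℓ)` is always reached; contamination reads are emitted on top
  (each emission is RANDOM with probability 0.05), so nominal coverage
  refers to genome-derived reads and the RANDOM fraction remains
  binomial(n, 0.05).
- **Read length is fixed**, not a draw from a distribution: length
  distributions are simulator-internal details, and fixed length keeps the
  read-count and coverage oracles exact.
- **Paired-end inserts** are Normal(500, 50), truncated to
  [read_length, genome length]; mates face each other. No insert size is
  prescribed by the workflow, 500 bp is a common library target.
- Quality strings are constant at Q = round(−10·log₁₀(error_rate))
  (Phred+33), since the error process is homogeneous.
- `homopolymer_mode` (off by default) re-weights read errors toward indels
  inside homopolymers ≥ 3 bp, a placeholder for pyrosequencing-style error
  profiles; it is not calibrated and excluded from all benchmarks.

Byte-determinism: identical seed and inputs give identical FASTQ and truth
TSV, enforced by a single seeded generator and fixed iteration order.

## Baseline assembly

Canonical de Bruijn unitigs: k-mers (k = 31, odd so a k-mer never equals its
reverse complement) are counted in canonical form with a 2-bit encoding,
nodes below an abundance floor are pruned, and contigs are maximal
non-branching paths emitted in deterministic (lexicographic start) order.
An isolated simple cycle — a completely reconstructed circular genome — is
emitted once with `circular_flag` set; its spelled sequence ends with the
k−1 wrap overlap so the first and last (k−1)-mers coincide. No bubble
popping, tip clipping or scaffolding is attempted: the assembler exists to
make the pipeline testable and deterministic, not to compete with production
assemblers.

**Abundance floor.** Exact reads keep every k-mer (floor 1). For
error-bearing reads the floor is 4, derived from the error model rather than
tuned: a floor of 2 removes singleton error k-mers but not *duplicated*
errors — two reads erring at the same site to the same base, probability
(e/3)² per read pair, hence hundreds of such sites at e = 0.02 and ≥ 20×.
Each survivor branches the graph and shatters unitigs, and because the
number of duplicate pairs grows quadratically with depth, a fixed floor of 2
makes assemblies *worse* with more coverage. Multiplicity ≥ 4 duplicated
errors are not expected below ~100×, so 4 removes the error bands across
desk-scale depths. The flip side: genomes covered below roughly 25× lose
true k-mers (k-mer depth ≈ 0.43 × read depth at 150 bp reads) and fragment —
consistent with the observation the simulations are designed to show, that
150 bp reads need ≥ 40× for large contigs.

**Known limitation — conserved-region fragmentation.** When ~10 related
genomes (pairwise p ≈ 0.2, with rRNA/tRNA regions several-fold more
conserved) are pooled, each genome shares several hundred canonical 31-mers
with its pool-mates (a 31 bp window survives both branches of a 0.92-identity
region with probability ≈ 0.92³¹ ≈ 8%). Every shared k-mer is a branch point,
so even with exact reads the best single contig per genome spans ~0.2–0.5 of
its length, while total (multi-contig) coverage stays ≈ 95% and contigs still
demultiplex perfectly. Recovering chromosome-scale contigs from such pools
requires haplotype-aware graph cleaning, deliberately out of scope here; the
end-to-end suite asserts the full workflow targets including
single-contig spans and therefore documents this gap honestly rather than
papering over it.

## Demultiplexing and evaluation

Assignment score of a contig for a taxon is the *containment* of a reference
marker in the contig: |shared canonical 15-mers| / |marker 15-mers|,
maximised over the taxon's markers; k = 15 is specific at mitogenome scale
yet tolerant of the ≥ 15% between-specimen divergence a pool guarantees. A
contig is assigned when the best score ≥ 0.2 and ≥ 2× the runner-up; exact
ties are ambiguous. Under the default pool policy these defaults make
cross-assignment empirically impossible in the suite (100% of assigned
contigs map to their true genome); all three are configurable.

Truth mapping aligns each contig (both orientations) to the doubled truth
sequence with edlib infix alignment — doubling makes origin-spanning
placements exact — after shortlisting genomes by shared 15-mers (≥ 5).
A contig is chimeric when ≥ 2 genomes each cover ≥ 500 contiguous bases of
it (15-mer runs merged across ≤ 50 bp gaps) at ≥ 90% identity. The overlap
summary reports, per truth genome, the best single-contig fraction and the
circular-union covered fraction, against the genome's own length (default)
or a fixed 16,400 bp average (for comparability with report conventions that
use a constant denominator); threshold counts (> 33/50/66%) use strict
inequalities. Two contigs jointly tiling a split circle are reported per
contig, never merged.

`tetra_profile` exposes sliding tetranucleotide frequencies (256-vector,
lexicographic order, N-containing windows skipped) for composition-based
exploration; no clustering/SOM layer is built on top of it since composition
showed little structure at this scale.

## Synthetic families

The generator emulates the one property of real mitogenome families the
workflow depends on: a circular genome with a conserved/variable mosaic.
The default layout (~15.6 kb) is a vertebrate-like gene order starting at
COI (1,545 bp): 13 protein-coding genes, 2 rRNAs (810 + 1,480 bp), 22
interleaved tRNAs (68 bp), control region (800 bp). Relative substitution
rates per class — PCG 1.0, rRNA 0.3, tRNA 0.5, CR 2.0 — reproduce the
qualitative conservation ranking (rRNAs least variable, control region
fastest); they are configuration, not biological estimates.

Descendants are drawn on a **star phylogeny** with **exact substitution
counts**: per region, `round(length × target × multiplier / weighted-mean
multiplier)` distinct sites are changed to a different base, so the realized
ancestor divergence is a constant (±rounding), not an expectation — which
turns divergence targets into testable equalities. Expected leaf-to-leaf
divergence is 2t(1 − 2t/3) (sites coincide when untouched on both branches
or doubly hit to the same base). Optional short indels (1–10 bp, geometric)
are excluded from the Folmer window so the COI proxy stays well defined.
Ancestors re-draw until free of duplicate 31-mers, so single-genome assembly
is repeat-free by construction.

What the synthetic families do *not* model: codon structure, compositional
bias, gene rearrangements, tRNA secondary structure, heteroplasmy, or
between-branch rate variation. Benchmarks passing on these families
demonstrate the pipeline's mechanics and bookkeeping, not performance on any
real taxon; in particular real families with unusually conserved segments
(e.g. a ~200 bp identical 16S stretch between congeners) will behave like
the rRNA-fragmentation case above or worse.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: 10-specimen families at
branch divergence 0.12 (pairwise ≈ 0.21, all COI proxies ≥ 0.15); exact
reads 160 bp every 4 bp (40×) and simulated reads 150 bp at uniform 40× or a
10×–28× ladder, 3 seeds; clique/colouring oracle batches of 200 × 12-node
and 100 × 8-node instances; 1,000 random gapped pairs for the p-distance
oracle; 50 pairs for the window-variance comparison (one-sided sign test,
α = 0.01). These sizes keep a full run in the minutes range on one CPU while
leaving every statistical check comfortably powered.
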