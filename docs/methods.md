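# Methods

mitekit implements the computational workflow used to characterize a
*Tourist*-like MITE family in plant genomes: find copies of a known element,
validate their transposon structure, and carry the family through the
downstream analyses such a study reports.  This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
data does and does not establish.

## The element model

A *Tourist*-like MITE copy is modelled as

```
... flank | TSD | left TIR · AT-rich core · right TIR | TSD | flank ...
```

* **TSD** — a 3-bp target-site duplication: the host triplet present once at
  the pre-insertion site and duplicated on both sides of the element by the
  insertion mechanism.  *Tourist*-like families canonically duplicate TAA,
  but the detector accepts any duplicated triplet by default (a
  `tsd_motif="TAA"` filter is available), because family classification in
  MITE databases rests on TSD presence generally.  N never satisfies a
  duplication.
* **TIR** — terminal inverted repeats: the element's first L bases pair
  (Watson–Crick, read antiparallel) with its last L bases.  The family this
  package models has 14-bp TIRs (consensus `GGGTCTGACTGGTT`) of which 10 of
  14 positions are complementary between the two arms.
* **Core** — an AT-rich interior (family mean ≈ 67% AT over ≈ 545 bp)
  containing a long contiguous A/T run (≈ 270 bp in the reference copy).

A copy is **complete** when it carries a duplicated TSD and a qualifying TIR
pair; the alternative TSD-only definition is available
(`completeness="tsd"`) since the field sometimes defines completeness by
TSDs alone.

## Discovery: seed-and-extend scanning

The scanner searches both strands of each chromosome with the family
consensus.  Exact shared k-mers (default k = 12) nominate candidate regions;
each region, padded by 30 bp, is resolved with an affine-gap Smith–Waterman
alignment of the full query (match +1, mismatch −2, gap of length k scores
−(4 + k)).  Because the window is guaranteed to contain any alignment seeded
inside it, the reported hit interval, score and identity equal a full
Smith–Waterman run over the same sequence pair; the test suite asserts this
against an independent implementation (Biopython's `PairwiseAligner`).  Hits
below 70% identity or 50% query coverage are dropped (deterministic,
database-size-independent thresholds standing in for a BLAST e-value
cutoff); overlapping same-strand hits keep the best score, ties breaking to
the leftmost start and then the + strand.  The DP kernels are row-vectorized
with numpy; the within-row gap dependency is a prefix-max scan, so no
quadratic Python loop survives.

### TIR calling

For arm lengths L from 10 to 20, the element prefix of length L is paired
against the reverse of its suffix of length L, counting complementary
positions.  Among lengths with at most 4 mismatches, the call maximizes the
paired count, breaking ties toward fewer mismatches (hence shorter arms).  A
longest-first rule was rejected: with AT-rich interiors, the 1–6 core bases
adjacent to a perfect 14-bp TIR pair by chance often enough that a
longest-qualifying rule systematically reports inflated arm lengths for
textbook-perfect elements.

### Boundary refinement and completeness

Alignment end-points wobble by a few bases when a copy is diverged or
truncated, so every boundary placement within ±6 bp of each hit edge is
scored by the tuple *(TSD duplicated, TIR qualifies, smallest shift, TIR
paired count)*, in that priority.  Two deliberate choices here:

* **A qualifying TIR needs ≥ 10 paired positions** in addition to ≤ 4
  mismatches.  At the short end of the arm range a mismatch-only rule
  accepts arms with as few as 6 paired positions, which AT-rich sequence
  achieves by chance at a per-locus rate of several percent across the
  refinement grid — enough to misclassify truncated copies as complete.
  Ten paired positions is also exactly the pairing level of the family's own
  14-bp TIR.
* **Smallest shift outranks raw paired count.**  A duplicated TSD pulled
  inside the arms always contributes extra chance pairings (the two TSD
  copies are identical, so roughly two of three positions pair), so
  maximizing paired count alone drags boundaries outward systematically.

With both TSDs and TIRs present (intact copies), refinement recovers planted
boundaries exactly.  A truncated copy has no structural signal on its broken
side; its boundary is recovered to within the alignment's chance-extension
(a few bp), and its completeness call is still exact.

### Hairpin folding

`fold_max_pairs` is a Nussinov-style base-pair maximization DP over
Watson–Crick pairs (G·U optional, off by default for DNA input) with a
minimum hairpin loop of 3; it returns the maximal pair count and one
deterministic dot-bracket traceback.  It is exact — verified against
exhaustive enumeration for short sequences — and quadratic in memory, cubic
in time, so inputs are capped at 2 kb; precursor assessment uses ~90–120-nt
windows where this is instantaneous.

## Family statistics

Densities are elements per Mb with Mb = 1e6 bp exactly.  Report rounding is
decimal half-up (2 decimals for densities, 1 for percentages) and unrounded
values are kept alongside, because table-level rounding alone can shift a
printed figure by 0.1.  The composition summary uses the sample (n−1)
standard deviation; AT-content denominators exclude N.  The length/AT
correlation is Pearson's r with the two-sided p from the t transform on n−2
degrees of freedom; degenerate inputs raise rather than returning NaN.  The
TIR consensus matrix trims detected arms to a fixed length (default 14,
anchored at the element end), excludes shorter arms with a count, and writes
IUPAC codes at tied positions.

## Phylogeny

The multiple alignment is guide-tree progressive: all pairwise global
alignments (match +1, mismatch −1, linear gap −2) give p-distance guide
distances; a UPGMA guide tree (ties to the smallest index pair) orders
profile–profile merges scored by integer sum-of-pairs.  This is a basic
progressive aligner, adequate for intra-family element sets that are
globally alignable; it makes no claim to ClustalW output equality.

p-distances use pairwise deletion by default (sites with a gap or N in
either row are excluded per pair); complete deletion is available.  A pair
with no comparable sites is an error naming the pair.

Neighbor joining is the canonical agglomerative algorithm: at each step the
pair minimizing Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·) is joined, with
ties broken by the lexicographically smallest pair of cluster
representatives (a cluster is represented by its smallest leaf label), so
the tree is label-permutation invariant up to isomorphism.  Branch lengths
follow the standard formulas; negative lengths are clamped to zero and
logged (display behaviour matching common phylogenetics GUIs).  On additive
matrices NJ reproduces the generating tree's topology and path lengths to
1e-9 (asserted for 4–8 taxa).  Bootstrap support resamples alignment columns
with replacement, rebuilds the NJ tree per replicate, and reports the
percentage of replicates containing each internal bipartition of the
point-estimate tree; 1000 replicates by default, reducible for desk-scale
runs.  Replicates that leave a pair with no comparable sites are skipped and
removed from the denominator.

## Insertion context

Distance is nearest-edge to nearest-edge (bases strictly between the
intervals).  An element overlapping a gene span is category `gene` with
distance 0; its sub-feature is `intron` when fully inside one, otherwise the
majority-overlap feature with UTR overlap carved out of exon overlap.
Otherwise the nearest gene (ties toward the 5′-flank assignment, then the
lower gene id) sets the side — by the gene's strand only — and the distance
bins are half-open: [0, 1000), [1000, 2000), [2000, 3000); 3000 bp or more
(or no gene on the chromosome) is intergenic.  "Gene-rich" aggregates
everything except intergenic.  Percentages are half-up to 1 decimal.

Transcript fragment placement aligns the transcript to the element (both
orientations) to find the element-derived block, places that block on the
genome around the gene locus by local alignment (splice-unaware — the block
is contiguous in both transcript and genome for UTR and intron-retention
cases), and labels it by majority overlap among 5′UTR / 3′UTR / intron /
CDS; anything below 20 aligned bases or 80% identity is `unplaced`.

The locus genotyper is the in-silico analogue of a flanking-primer PCR
assay.  Anchors (≥ 18 nt, unique in the genome, both strands searched) play
the role of primers; the "product size" is the anchor-to-anchor span.  A
locus is `present` when the intervening segment matches the element at
≥ 70% identity and ≥ 50% coverage with a duplicated TSD immediately inside
the anchors; an intervening gap under 50 bp is the pre-insertion allele
(`absent`); anything else — missing or multiple anchors, an unrecognizable
segment — is `no_data`.  The 50-bp tolerance separates excision footprints
from unrelated indels.  The diagnostic size difference between alleles is
element length + 3 (the duplicated triplet).

## Methylation

Clone sequences are aligned to the untreated reference with a
conversion-aware global alignment: reference C against clone C (methylated)
or T (converted) is free; any other substitution costs 1 and gaps cost 2.
Clones under 80% conversion-aware identity are rejected with a warning.
Only the assayed strand is called, matching Sanger-clone bisulfite designs.
Per reference C, clones showing C count methylated and T converted; gaps and
other bases are excluded from that clone's tally.  Contexts are CG, CHG, CHH
(H ∈ {A, C, T}) read from the reference; positions too close to the region
end to be determined fall back to CHH.  Region (element vs flank, split at
the element span) and context aggregates are weighted levels
Σmethylated/Σtotal.  A known-unmethylated control region yields conversion
efficiency = 1 − unconverted/total; below 0.95 the whole report is flagged
low-confidence, since conversion failure inflates apparent CHH methylation
indistinguishably from real signal.

## Small RNAs

Matching is exact sliding-window Hamming comparison on both strands (U→T on
input; N never matches), queries 18–30 nt, default mismatch budget 1 for
element scans and 0 for transcript scans.  Coordinates are reported 1-based
inclusive in element-forward orientation, so the span length always equals
the query length.  Precursor assessment folds a window anchored at the
match's 5′ end (default 120 nt, truncated at the element end with a warning)
by base-pair maximization — the assessment is structural pairing, not a
thermodynamic minimum-free-energy model — and passes when the fold reaches
`min_pairs` (default 16) with no base pair joining two positions inside the
mature match (the mature sequence must sit on one arm of the stem).

## Synthetic data: what it emulates, what it does not

The generator produces every input with ground truth: i.i.d. background
chromosomes at a stated GC (default 35%, plant-like); a family consensus
(14-bp TIR + AT-rich core with one contiguous A/T run + reverse-complement
TIR; defaults 545 bp, 67% AT core, 270-bp run — the reference family's
figures); copies planted with real TSD mechanics (the target triplet is
duplicated around the insertion; `tsd_motif` forces TAA), per-copy
substitutions at a stated rate (default 2%) sparing the TSDs, optional
5′-truncation removing the left TIR; genes with exons/introns/UTRs placed
to realize a planned context category and distance per copy; bisulfite
clone sets with per-context methylation rates (defaults CG 0.8 / CHG 0.4 /
CHH 0.1 inside the element, 0 on flanks) and a conversion-efficiency
parameter; multi-genome presence/absence panels with shared flanks; and
spliced transcripts with optional intron retention.

Desk-scale default: 2 chromosomes × 200 kb with 20 copies each.  Planted
loci keep a minimum spacing of 7.8 kb and a 4.7-kb chromosome-end margin so
that a neighbouring locus's planned gene (which can reach 2.9 kb + 1.2 kb
from its element) can never sit within 3 kb of another element — this makes
planned context categories exactly recoverable, which the tests exploit.

Not emulated: indels within copies (substitution + truncation only), nested
or clustered insertions, segmental duplications and repeats other than the
planted family, transposition bursts or any explicit evolutionary process,
sequencing error in clones or transcripts, and alternative isoforms beyond
single-intron retention.  Passing tests therefore establish correctness of
the algorithms under a clean insertion model — alignment equivalence,
structural-call logic, exact plan recovery, parameter recovery within
binomial sampling error — not detection power on real genomes with nested
repeats, indel divergence or assembly artifacts.

## Determinism and degenerate inputs

Every stochastic routine takes an explicit seed (numpy `default_rng`; no
global state) and is bitwise-reproducible under it.  All DP tie-breaks are
fixed (diagonal > up > left; NJ lexicographic pairs; UPGMA smallest index).
Empty catalogs, empty clone sets, degenerate correlations, pairs without
comparable sites, and intervals without flank room raise typed errors rather
than returning NaN or silent defaults.  Internal coordinates are uniformly
0-based half-open; GFF3 and human-facing reports are 1-based inclusive, BED
is 0-based half-open, and conversion happens only in the I/O layer.

## Problem sizes in the shipped checks

The automated checks run the scanner on ≤ 0.5 Mb of synthetic genome,
alignment-oracle comparisons on ≤ 10 kb instances, folding-oracle
comparisons to length 12 (exhaustive enumeration), NJ recovery to 8 taxa,
a 504-copy context plan across 6 × 700 kb chromosomes, 10-clone bisulfite
sets over ≤ 500-bp regions, and 5-genome polymorphism panels — sizes chosen
so the whole pipeline exercises every code path in seconds while the
statistical recovery checks retain enough trials for tight binomial bounds.
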