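# Methods

This note documents the procedures karyoscan implements, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the design choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversion happens only at
I/O boundaries. BED is consumed as-is; RepeatMasker `.out` tables are
whitespace-delimited with header lines skipped by pattern and begin/end
columns read as 1-based inclusive. FASTA goes through Biopython; sequences
are upper-cased on read and restricted to A/C/G/T/N.

## Local similarity search

The empty-site caller, deletion classification, TIR detection and
source-copy attribution all rest on one local-alignment primitive with a
fixed contract rather than on an external search tool.

* **Scoring**: match +1, mismatch −2, linear gap −3. Identity is
  matches / alignment columns, so gaps count against identity — the
  convention the pipeline's 99 % threshold presumes. N never matches
  anything, including another N, so N runs cannot manufacture identity.
* **Seeding and extension**: exact 15-mer anchors against a reusable
  subject index, grouped into diagonal clusters (anchors within 100
  diagonals); each cluster is extended with a banded Smith–Waterman
  (band = cluster diagonal range ± 150), which bounds the indel size an
  alignment can absorb at 150 bp — far above the TSD-footprint indels
  (≤ 20 bp) the procedures need to bridge. Queries shorter than 2 kb fall
  back to exhaustive full-matrix DP when no anchor is found. Clusters with
  fewer than 3 anchors on queries ≥ 200 bp are not extended: a genuine hit
  long enough to pass any downstream filter seeds many anchors, while
  isolated anchors are chance 15-mer collisions.
* **Determinism and ties**: equal-scoring alignments resolve to the smaller
  subject coordinate, then the smaller query coordinate; traceback prefers
  diagonal over vertical over horizontal moves. Hits are reported by
  descending score with the same tie order. The test suite checks the
  implementation against an independently written full-matrix DP oracle on
  planted instances where the optimum is unique.
* **TIR detection** aligns the 5′ end of an element against the reverse
  complement of its 3′ end, ungapped; the reported TIR is the
  maximal-scoring terminal segment (match +1 / mismatch −1, ties to the
  longer segment), subject to a minimum length (default 10 bp) and identity
  (default 80 %). An ungapped definition keeps the statistic exact and
  matches how TIRs are read in practice; terminal indels in a TIR would
  shorten the reported repeat rather than extend it.

## Empty-site calling

For every annotated TE strictly longer than 120 bp, 5,000 bp flanks are
extracted on both sides (truncated flanks are flagged; loci whose flanks
cannot reach the 4,500 bp alignment floor are skipped with a logged reason
rather than re-thresholded per locus, keeping the printed thresholds
bit-exact). A locus is a **putative** empty site in a target assembly when
the best hits of the two flanks land on the same contig, same orientation,
with an inner distance of at most 20 bp; small overlaps down to −20 bp are
allowed because deletion breakpoints may chew into the junction (the
procedure's prose does not settle this; the choice is recorded here). The
junction is the midpoint of the inter-hit interval.

Confirmation re-searches the concatenated left+right flank (10 kb at the
defaults) and requires **exactly one** hit at ≥ 99 % identity over
≥ 9,000 bp. The single-hit rule is what rejects paralogous loci. Homologous
loci found in different pairwise comparisons are clustered by reciprocal
flank homology (≥ 95 % identity over ≥ 1 kb, or a shared donor copy) and
split wherever calls in one genome lie more than 70 kb apart; the span cap
implies a maximum detectable insertion of 70,000 − 9,000 = 61,000 bp.

TSD detection is exact-match only (≤ 20 bp): the longest word that ends the
inserted sequence and also immediately precedes the junction. The
sequence-pair form (`detect_tsd`) locates the insertion from the longest
common prefix/suffix of the filled and empty locus and flags junctions whose
placement is not unique (e.g. homopolymer runs) as ambiguous. Exact matching
is the testable codification of what is otherwise a visual-inspection step.

## Variant filters

* Size: calls ≥ 50 bp are retained; translocations always pass (undefined
  length).
* Fixed/mosaic: a variant is *fixed* iff fewer than 3 reads carry the
  reference allele; the mosaic fraction alt/(alt+ref) is always reported.
  The rule is applied per variant (not per breakpoint).
* Consensus: ≥ 3 distinct caller modules (set semantics).
* Uniqueness: a call survives only if its interval intersects no call from
  any other sample; insertions count as breakpoints ± 100 bp since
  breakpoint coordinates jitter between callers.
* `apply_filters` combines the three with intersection semantics: every
  filter — uniqueness included — is assessed against the complete input
  call set, so the combination is independent of any ordering. Sequential
  composition would not be: removing a sub-threshold call first would also
  remove its veto over an overlapping call in another sample.
* Deletion mechanisms: boundaries matching an annotated copy within ± 10 bp
  → TE excision (excision footprints are imprecise, hence the tolerance);
  removal of internal sequence plus one LTR of an LTR element (either side)
  → solo-LTR; breakpoints in two distinct same-family copies spanning
  roughly one copy plus the intervening sequence (± 25 % relative) →
  inter-copy NAHR, with the pair's relative orientation recorded; otherwise
  other.

## Recombination scan

Two clonal nucleotype groups are compared over a sorted biallelic site
list. Per-group consensus is the majority allele (ties → missing). A site
is discordant for a focal sample iff its call differs from its own group's
consensus *and* equals the other group's, all three non-missing. Candidate
tracts are maximal runs of ≥ 2 consecutive discordant sites; "consecutive"
means adjacency in the filtered site list within a contig, not base-pair
distance. Missing or masked sites break runs — the mask stands in for the
read-level visual review of mapping quality that the scan cannot reproduce
computationally. π is average pairwise differences per callable site over
all sample pairs, with the callable length supplied by the caller rather
than taken from assembly size.

## TE load

Depth over each family consensus is normalized by 35 / (observed
single-copy median); the factor is capped at 1 because subsampling cannot
add coverage (the cap is logged). Presence requires ≥ 15× depth across
≥ 90 % of consensus positions; absent families are coded 0. The median is
taken over *all* consensus positions (the procedure's prose does not say;
this is the recorded choice). CV is the sample standard deviation (n−1,
appropriate at n = 7 samples) over the mean; families above the type-7
(linear-interpolation) third quartile are flagged. Normalization is applied
as a multiplicative factor on depth vectors rather than literal read
subsampling: the statistic depends only on depth, and this keeps the module
alignment-free.

## Methylation

Per-read calls are kept only from reads with mapq ≥ 60, primary alignments,
and a contiguous aligned reference span ≥ 6,000 bp ("uninterrupted mapping
distance" codified as aligned span with clipping excluded — an
interpretation, flagged as such). Site frequency is methylated/total calls
per CpG. The repeat vs non-repeat contrast labels sites by interval
overlap (non-repeat = complement of the repeat intervals) and, by default,
draws 500 balanced subsamples of the two classes (subsample size 80 % of
the smaller class), applies a two-sided Wilcoxon rank-sum test to each, and
summarizes statistic and p by their medians. "Downsampled 500 times" could
equally mean a 500-fold size reduction; that reading is available as
`mode="fold_reduction"` and the default is a documented choice, not a claim
about intent.

## The synthetic-data generator

The generator's defaults are the study conditions the rest of the package
is tested under:

* **Genome**: one 200 kb contig, GC 0.47, i.i.d. background. Real genomes
  have compositional heterogeneity and segmental duplications that i.i.d.
  background does not emulate; false-positive behaviour on such structure
  is outside what the tests can show.
* **TE library** (five families): an autonomous 3,396 bp hAT-like DNA
  transposon and a 2,765 bp nonautonomous partner sharing a 28 bp TIR
  (nonautonomous elements must carry their partner's TIR to be mobilised),
  a 1,120 bp Mariner-like element (30 bp TIR, TA-like 2 bp TSD), a 4 kb
  LINE planted with per-copy 5′ truncation (uniform 10–60 %), and a
  4.8 kb LTR element with two identical 300 bp LTRs, one pair planted
  2.5 kb apart as NAHR substrate. TSD lengths (8/2/10/5 bp) are
  generator parameters — characteristic of the superfamilies but not
  dictated by any measurement.
* **Copies**: 17 ancestral copies (2/5/5/3/3 per family), planted in
  shuffled order with uniformly distributed gaps, ≥ 6 kb separation and
  ≥ 6 kb edge margins so every locus has clean 5 kb flanks; each copy sits
  between two copies of its TSD; copies diverge by 0.3 % substitutions
  (LTRs protected so the two LTRs stay identical).
* **Events**: two protoclone-like samples with 5 insertions + 5 clean
  excisions each (20 scorable events per simulation), and a third sample
  carrying one solo-LTR deletion, one inter-copy NAHR deletion and one
  inversion. Insertions copy an existing ancestral copy verbatim and add
  the family TSD; excisions remove the annotated TE and leave the doubled
  TSD footprint. Event loci keep 6 kb clearance from each other; targets
  are drawn uniformly from the remaining free intervals, which makes
  placement feasible for every seed rather than by rejection.
* **Mosaicism**: each event is fixed (fraction 1.0) with probability
  12/72 — the observed fixed:mosaic split among the protoclone variants —
  otherwise its fraction is uniform on (0.1, 0.9). Read support is
  Binomial(40, fraction); caller agreement grows with the fraction.
* **Depth**: negative binomial (dispersion 8) with mean copy number × raw
  coverage, where each sample's raw single-copy coverage is a uniform
  1.2–2.5× multiple of 35× (so the normalization path does real work), and
  a 2 % cross-mapping floor keeps absent families near but not exactly
  zero.
* **Methylation**: per-site latent frequencies Beta-distributed around
  class means 0.76 (repeat — the protoclone repeat-space mean) and 0.20
  (non-repeat: no genome-wide non-repeat mean is reported; 0.20 is a
  typical unmethylated background and is a generator parameter, not an
  assertion), concentration 8, ~20 reads per site over the genome's actual
  CpG positions; 5 % of reads fail each mapping filter.
* **Genotype matrices**: group A carries allele 0 and group B allele 1 at
  every site; protoclones of a nucleotype are clonal, so within-group noise
  defaults to zero and calls go missing at 1 %. The default site count
  (1,000 over a 100 kb callable length with 4+4 samples) is calibrated so
  expected π matches the ~0.56 % divergence between the two nucleotypes.
  Planted recombination tracts swap a block of consecutive sites in one
  sample.

Everything is a pure function of (config, seed) via spawned NumPy
`SeedSequence`s; the acceptance script derives all its seeds from its
`--seed` argument.

## Problem sizes

The test suite and acceptance script run the recovery experiment at 20
planted clean events per simulation across 3 seeds (60 events), the oracle
comparison on 50 planted instances ≤ 2 kb, the mosaic-fraction calibration
at 200 replicates per fraction, the null calibration of the rank-sum
comparison over 200 seeded datasets, and the CV rank-order experiment over
50 (tests) / 20 (acceptance script) replicates of 7 samples × 8 families.
These sizes are the package's chosen desk-scale study conditions.

## Known limitations

* The similarity search is built for assemblies of this scale (hundreds of
  kb); it indexes subjects in memory and is not a genome-scale aligner.
* Homologous-locus clustering splits oversized groups at per-genome gaps
  greater than the span cap (single-linkage style); pathological chains
  could still leave a cluster whose extreme members exceed the cap.
* The recombination scan cannot reproduce the visual mapping-quality
  review it replaces; the mask option is the hook for an external
  mappability judgement.
* Deletion-mechanism classification assumes the annotation set describes
  the genome the deletion coordinates refer to; nested or fragmented
  annotations can shadow the copy-boundary match.
* The generator plants events in non-repetitive context by construction;
  recovery rates measured on it say nothing about nested insertions,
  tandem arrays, or low-complexity junctions beyond the flagged cases.
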