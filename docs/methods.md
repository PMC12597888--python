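# Methods

## Background and scope

Plasma cell-free DNA (cfDNA) is fragmented nonrandomly: nucleases cut
preferentially in linker regions between nucleosomes, so fragment
coordinates, sizes, and end sequences carry positional and regulatory
information. `fragkit` extracts the standard fragmentomic features from
aligned-fragment data — fragment length distributions, binned coverage, raw
and adjusted window protection scores (WPS), DELFI-style short/long ratios,
5′ end motifs and the motif diversity score (MDS), breakpoint motifs, and
cleavage proportion profiles — genome-wide or over arbitrary intervals, and
includes the interval-MDS classification analysis and synthetic-data
generators that make every stage testable without external downloads.

Upstream preprocessing (trimming, alignment, duplicate marking) is out of
scope: inputs are coordinate-sorted, indexed BAM/CRAM files or
bgzip-compressed, tabix-indexed fragment TSVs ("frag.gz": contig, start,
end, mapq, strand).

## Coordinates, filters, and file dialects

All coordinates are 0-based half-open (the BED/frag convention). A fragment's
two breakpoints are its first covered base (`start`) and its last covered
base (`end − 1`). BAM pairs are collapsed to one fragment per properly-paired
pair using the read with positive template length; the fragment strand is
the strand of read 1. The mapq recorded is that of the representative read.

Default quality filters keep fragments with mapping quality ≥ 30, properly
paired, non-duplicate. The "more than 30" phrasing common in cfDNA pipelines
is ambiguous between `>` and `≥`; `fragkit` uses `mapq ≥ min_mapq` with
`min_mapq = 30`, configurable. Filters compose conjunctively. Written
fragment files are sorted by (contig in input order, start, end, strand) —
the strand tiebreak makes outputs byte-reproducible.

A fragment is assigned to an interval when its midpoint
`floor((start + end − 1)/2)` lies in the interval. Midpoint assignment makes
per-bin counts over a tiling an exact partition of the fragment total, which
is the property DELFI-style binned counting relies on; overlap counting is
available as an option where a different convention is wanted.

## Window protection score

Raw WPS at position *p* with protection window *w* (default 120 bp, with
fragments restricted to 120–180 bp, the mononucleosome range):

    WPS(p) = #{fragments spanning [p − w/2, p + w/2)}
           − #{fragments with ≥ 1 endpoint inside that window}

Conventions that the definition leaves open, fixed here: the window is
half-open; a fragment exactly coinciding with the window counts as spanning
(spanning takes precedence over endpoint membership); a fragment with both
endpoints inside the window contributes −1 once, not twice. Implementation
is by difference arrays (O(n) per fragment), with fragments fetched from a
margin of w/2 + max fragment length beyond the scored region so edge scores
are exact; the test suite holds it to exact equality with a brute-force
per-(position, fragment) oracle on hundreds of random instances.

Adjusted WPS subtracts a running median (window 1000 bp; at the track edges
the window shrinks symmetrically) and then applies Savitzky–Golay smoothing
(window 21, polynomial order 2). These defaults follow the convention of the
original nucleosome-footprint implementation; all are flags, and tests pin
the behavior (constant elimination, polynomial reproduction, agreement with
a direct per-point least-squares oracle) rather than the default values.

## End motifs, MDS, breakpoint motifs

Fragment files carry no sequence, so motifs are read from the reference at
fragment coordinates. Each double-stranded fragment has two 5′ termini: the
plus-strand motif is `ref[start, start+k)` and the minus-strand motif is the
reverse complement of `ref[end−k, end)`; both contribute by default
(`plus_only` is available for replicating single-end conventions).
Soft-masked bases are uppercased; motifs containing non-ACGT characters are
skipped and counted. Tables always span the full 4^k alphabet in
lexicographic order (k = 4 by default, 256 motifs).

MDS is the Shannon entropy of the motif frequency distribution normalized by
log(4^k) — 1 for uniform, 0 for degenerate; the log base cancels (natural
log internally). Intervals with zero motifs report a missing MDS, never 0.

Breakpoint motifs extend the end motif across the cleavage site: u bases
upstream plus d bases downstream of each 5′ breakpoint (defaults u = d = 3),
read in the breakpoint's own orientation (minus-strand contexts are
reverse-complemented). With u = 0 the operation reduces exactly to end
motifs with k = d, which the tests assert.

## DELFI short/long ratios

Fragments are counted per bin (default 100 kb) as short (100–150 bp) or long
(151–220 bp); these ranges follow the published DELFI convention and are
flags. Bin GC content is computed from the reference with N bases excluded
from the denominator. GC correction fits a locally-weighted linear
regression (tricube weights, span 0.75, via `statsmodels` lowess) of count
on GC separately for short and long counts; corrected = raw − fitted +
mean(fitted), clipped at zero. Centering on the fitted mean preserves the
global mean exactly before clipping. A local-linear fit reproduces a count
profile that is linear in GC exactly (interior bins), which is the
correction's acceptance property; with no GC-dependent sampling the
correction is a near-no-op. Bins with fewer than two distinct GC values skip
correction with a warning; ratios with a zero denominator are reported as
missing (NA), never 0 or infinity.

## Cleavage proportion

At genomic position *p*: the number of fragment termini located exactly at
*p* (both termini of every fragment count; the right terminus is at
`end − 1`) divided by the number of fragments covering *p*
(`start ≤ p < end`). Counts are pooled across sites after minus-strand
reversal and divided once — pooling stabilizes low-depth positions and is
deliberately not the mean of per-site ratios (a two-site test distinguishes
the two orders); a per-site mode is available. In phased chromatin, cleavage
concentrates in linkers while WPS peaks over protected cores, so the two
aggregate profiles around nucleosome anchors are anticorrelated; the test
suite reproduces this on synthetic phased data (r ≈ −0.8).

## Interval-MDS classification

The pipeline mirrors the standard interval-feature cancer-detection
analysis: a samples × intervals MDS matrix with binary labels is evaluated
by stratified 10-fold cross-validation repeated 10 times
(`RepeatedStratifiedKFold`, seeded, so the identical split sequence can be
reused across feature sets for paired comparisons). Within each fold, the
top-k features by one-way ANOVA F statistic are chosen on the training
portion only; an L2-penalized logistic regression (C = 1.0, tol = 1e−4,
lbfgs, ≤ 100 iterations, no class weighting, no feature scaling — MDS values
are already commensurate in [0, 1]) is fit on the training portion and
scores the held-out samples. The fold AUC is the rank-based (Mann–Whitney)
ROC AUC, P(score_case > score_control) + ½·P(tie); the reported AUC is the
mean over all folds and repeats (a pooled-per-repeat mode exists). Features
with zero within-class variance and nonzero between-class variance receive
an infinite F and rank first; ties break by feature order. The ANOVA F and
rank AUC are computed in-package and cross-checked in tests against
scikit-learn's `f_classif` and `roc_auc_score`.

Leakage control is structural — selection sees only training indices — and
is tested adversarially: a planted feature equal to the label on a fold's
held-out samples but noise on its training samples is never selected.

## Synthetic data: what it emulates, what it does not

The generators encode the statistical structure the features assume:

- **Lengths**: a Gaussian nucleosomal mode (mean 167 bp, sd 10 bp — the
  canonical cfDNA modal length) plus an optional sub-nucleosomal comb:
  narrow peaks at `round(167 − 10.4·j)`, j = 2..8 (all below 150 bp), with
  geometric weight decay 0.7 and total comb mass 0.25. The comb reproduces
  the qualitative 10.4 bp ladder of the short-fragment shoulder for testing
  periodicity detection; it does not claim biological fidelity of peak
  weights. Note the rounding makes the realized mean peak spacing ≈ 10.33 bp.
  Lengths are clamped at ≥ 30 bp.
- **Placement**: fragment midpoints uniform, or normal around planted
  nucleosome centers (sd 20 bp by default) to emulate phasing.
- **Reads**: mapq fixed at 60 so default filters are pass-through in clean
  tests; a "dirty" mode injects low-mapq records and exact duplicates to
  exercise filters. A minimal BAM writer encodes fragments as proper pairs
  for dialect-equivalence tests.
- **Cohorts**: control interval-MDS ~ 0.95 + N(0, 0.01), cases shifted by
  −0.05 in 100 of 500 intervals, 25 samples per group, clipped to [0, 1] —
  a deliberately strong planted effect (5 noise sd per affected interval)
  under which the pipeline should approach perfect discrimination, with a
  label-permuted null near 0.5.

Synthetic references are uniform ACGT, so end-motif tables on synthetic data
are near-uniform (MDS close to 1) and carry no sequence-dependent cleavage
bias; real cfDNA shows strongly non-uniform end motifs. Passing tests
demonstrate correctness of the computations and the planted-structure
recovery loop, not biological realism of any distribution.

## Numerical and design choices

- Running median edges shrink symmetrically (window radius min(r, i, n−1−i)),
  so no padding values leak into the background estimate.
- Length-histogram mode ties break to the smallest length. The empirical
  argmax of a 50 000-draw sample from the 167/10 Gaussian fluctuates ±1–2 bp
  around 167 (adjacent 1-bp bins differ by ~0.5% in density); the acceptance
  script reports the raw argmax.
- The null AUC of the classification pipeline is estimated by averaging over
  several independent label permutations, because a single permutation draw
  dominates the variance of the null mean.
- Parallelism (`--workers`) chunks work units (intervals, sites, genomic
  pieces) at a fixed chunk size independent of the worker count and merges
  results in chunk order, so outputs are byte-identical for any worker
  count. Worker processes are forked and re-open inputs by path.
- Problem sizes in the test and acceptance suites (50 k-fragment length
  samples, 40 k-fragment phasing sets, 100 kb contigs, 10×10 CV on 50
  samples × 500 intervals) were chosen as the smallest sizes at which the
  statistical properties under test are stable.

## Known limitations

- CRAM requires the reference path to be supplied; no auto-download.
- BAM mate mapq is not consulted when collapsing pairs (single pass).
- No GC-bias correction for WPS/coverage; DELFI is the only GC-corrected
  feature, as in the published methods.
- The cohort generator models interval MDS values directly rather than
  deriving them from simulated fragments per sample; it tests the
  classification pipeline, not the end-to-end path from reads to AUC.
- Nucleosome peak calling, methylation inference from cleavage, and the
  DELFI machine-learning classifier are out of scope.
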