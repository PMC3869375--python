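# Methods

This note documents the models, parameter choices and numerical
conventions behind `enact`, and what the synthetic-data tests do and do
not establish about real data.

## Coordinates and overlap

All coordinates are 0-based half-open (BED convention).  Two regions
co-localize when they share at least 1 bp; half-open adjacency is not
overlap.  An interval's center is `floor((start+end)/2)`.  Interval sets
fed to co-localization counting must be internally disjoint — within-set
overlap raises an error rather than being merged silently, so Venn-style
counts are well defined.  Nearest-TSS ties at exactly equal distance go
to the lexicographically smaller gene id (a deterministic, arbitrary
rule; the case has measure zero on real data).

## Tag libraries

Mapped reads are reduced to *tags*: at most one read is kept per
(chromosome, 5′ position, strand) — configurable via
`redundancy_threshold` — and each retained read contributes a single
position at its 5′ end shifted by `fragment_size/2` (default 75 bp)
toward the fragment middle.  Coverage export (bedGraph / fixed-step WIG)
scales per-bin tag counts to reads per million.

## Island calling

The caller follows the island approach for broad enrichment domains:

* background rate λ = *N*·*W* / (*G*·*f*), with *N* total tags, *W* the
  window size, *G* the genome length and *f* = 0.74 the effective
  (mappable) genome fraction, configurable;
* a window is *eligible* iff P(X ≥ count; λ) < 0.2 (`eligibility_p`, a
  window-level prefilter — island-level significance is controlled
  separately);
* runs of eligible windows separated by at most `gap_windows` (default 1)
  ineligible windows form one island; gap windows contribute tag counts
  but not score; the island score is Σ −ln pmf(count; λ) over eligible
  windows;
* window size defaults: 200 bp for histone marks (H3K4me1/2/3, H3K27ac),
  50 bp for point-source factors (MLL4, C/EBPα/β, PPARγ, MyoD, MED1,
  Pol II).

Each candidate island is then scored against a control library: the
expected chip count is the depth-scaled control count, floored at the
genome-background expectation for the island span and at one tag.  The
background floor matters: candidate islands are selected for high chip
signal, and the control count over a short span is itself Poisson-noisy,
so taking its downward fluctuations at face value makes the test sharply
anti-conservative — on matched null libraries the unfloored test retains
about 1% of candidates at FDR 10⁻³, the floored test none, while strong
peaks (tens of tags over background) are unaffected.  The one-tag floor
additionally avoids zero-mean Poisson tests when the control is empty.
P-values are one-sided Poisson upper tails adjusted by
Benjamini–Hochberg; islands below the FDR threshold are retained
(10⁻³ histone marks, 10⁻¹⁵ factors vs input, 10⁻⁵ low-coverage
samples).  A no-control (random-background E-value) mode is deliberately
not implemented: every analysis here has a comparison library.

The knockout-based specificity filter re-extracts counts for each
retained island from the control-cell and knockout-cell libraries and
keeps islands where the control count significantly exceeds the
depth-scaled knockout count (one-sided Poisson, pseudo-count 1, BH
across islands, FDR < 10⁻¹⁵).  This removes antibody artifacts, which
show equal signal in both genotypes.

## Numerical conventions for extreme tails

Several statistics in this field are far below the double underflow
limit (p < 10⁻³⁰⁰), so all tail probabilities are computed and reported
in log10 space:

* Poisson upper tails use scipy where representable and otherwise a
  convergent ratio series on the log pmf; finite for |log10 p| well
  beyond 5000.
* Hypergeometric and binomial upper tails are log-gamma summations
  combined by log-sum-exp; they agree with exact rational enumeration to
  better than 12 significant digits of log10 p for N ≤ 60 / n ≤ 30.
* Benjamini–Hochberg is available on the linear scale (delegated to
  statsmodels) and on the log10 scale (hand-rolled, needed whenever
  p-values underflow); the two agree wherever both are representable.

The hypergeometric tail supports both the inclusive convention
P(X ≥ k) (the library default; P(X ≥ 0) = 1) and the strict convention
P(X > k) used by R's `phyper(..., lower.tail=FALSE)`.  The
dependence-enrichment operation uses the strict tail, which is the
convention the published worked-example statistics of this analysis
family follow; for the adipogenesis example the two conventions differ
by about one decade (10⁻²⁶⁶·⁸ vs 10⁻²⁶⁷·⁹).

Percentages are rounded half-away-from-zero to one decimal.  One quirk
worth recording: among the printed co-localization percentages this
pipeline family reports, "2,544 of 3,182 = 80.0%" is not reproducible by
exact arithmetic (2544/3182 = 79.9497… → 79.9); all other printed
percentages round exactly.

## Chromatin-state classification

Four mutually exclusive classes, promoters evaluated first:

* **promoter territory** is ±2,500 bp around a TSS (`promoter_radius`;
  the conventional distal cutoff — configurable because reasonable
  analyses use 1–5 kb);
* a TSS whose window overlaps an H3K4me3 island is a promoter, *active*
  if the window also overlaps H3K27ac, else *silent*;
* an H3K4me1 island whose center lies farther than the promoter radius
  from every TSS and which overlaps no H3K4me3 island is an enhancer,
  *active* iff it overlaps H3K27ac.  An H3K4me1 island inside promoter
  territory yields no element.

H3K4me2 is carried as an optional annotation mark but takes no part in
the class rules; the operative definitions use H3K4me1/3 + H3K27ac.
Pol II and MED1 are profiled signals only and enter no definition.

Peak-to-class distribution assigns each peak once, in priority order
active promoter > silent promoter > active enhancer > silent enhancer.
Lineage enhancer groups (C/EBP⁺PPARγ⁻, C/EBP⁻PPARγ⁺, C/EBP⁺PPARγ⁺) are
formed on active enhancers by 1-bp overlap, with C/EBP the merged union
of the C/EBPα and C/EBPβ island sets; MyoD-bound active enhancers are
the myogenic analog.

## Profiles and heat maps

Average profiles are depth-normalized tag counts in 5-bp bins from each
element center to 10 kb on both sides, averaged over centers; heat maps
use 50-bp bins with rows ranked by the ranking signal (e.g. MLL4) in the
central 400-bp window.  Profiles are not strand-oriented: enhancers have
no strand, and promoter profiles are left unoriented for consistency.
Only matrices/TSV are produced; figure rendering is presentation, not
computation.

## Expression analysis

RPKM = count / (exonic kb × mapped reads in millions), counting a tag
for every gene whose exon union contains its position.  A gene is
*expressed* with RPKM > 1 in at least one sample of the contrast under
analysis.  Regulation and dependence use the "over 2.5-fold" rule with
the boundary excluded; every ratio is stabilized by adding
`pseudo_rpkm` = 0.1 to numerator and denominator (how zero denominators
were handled historically is unstated; 0.1 RPKM is far below the
expression threshold, so the choice only affects genes that are
borderline silent).  Enhancer-to-gene assignment takes each grouped
active enhancer to its nearest TSS within 1,000 kb; a gene is
C/EBP⁺PPARγ⁺ if any associated enhancer is, otherwise the nearest
associated single-TF enhancer decides (the published rule does not
resolve the mixed single-TF case; nearest-wins is the natural extension
of the distance-based assignment); MLL4⁻ only if no associated enhancer
is MLL4⁺.  Group summaries report median/quartile log2 fold changes,
induced fractions (fold change > 2.5), and Wilcoxon rank-sum
comparisons (exact enumeration when the smaller group has ≤ 8 tie-free
values, otherwise the normal approximation with midrank tie correction
and no continuity correction, so identical groups give p = 1 exactly).

## Recovery analysis

Starting from reference C/EBPβ⁺ MLL4⁺ active enhancers, sequential 1-bp
overlap filters against the overexpression-condition island sets
(C/EBPβ, then MLL4, then H3K4me1 and H3K27ac) give the recovered set;
overlap with vector-condition MLL4 islands splits it into premarked and
de novo.  Reference intervals are used as-is (no re-centering).  The
MLL4 dependence of H3K4me1 on recovered enhancers is the fraction with a
significant (FDR < 10⁻³) one-sided decrease of depth-normalized H3K4me1
in knockout cells.

## Synthetic data

The generator plants, on a single 10-Mb chromosome, 500 genes (300
active + 200 silent promoters) and 450 enhancers (300 active, 150
silent) on a jittered grid, guaranteeing non-overlap and
enhancer–TSS distances beyond the promoter radius by construction, plus
50 antibody-artifact sites.  Active-enhancer occupancy: C/EBP 0.6,
PPARγ 0.25, jointly 0.15; an occupied enhancer is MLL4⁺ with probability
0.6.  Tag libraries hold 200,000 tags each — uniform background plus
50-fold enriched 600-bp peaks at occupied centers; knockout libraries
retain MLL4-dependent signal at 10%.  Expression is log-normal baseline
with negative-binomial counts (dispersion 0.04, a typical technical +
line-to-line replicate value); genes assigned to MLL4⁺ double-positive
enhancers are induced 4-fold at "day 2" and sit 8-fold below the
control day-2 level in the knockout (the generator's stated default
knockout effect size).  Recovery flags follow the chain
bound (0.65) → MLL4 (0.25) → active (0.9), premarked 0.35.  Every draw
derives from `SimConfig.seed` through fixed per-library substreams, so
identical configs give byte-identical fixtures.

Problem sizes were chosen so the complete pipeline — 20 ChIP libraries,
4 RNA samples, all stages — runs in well under a minute on one CPU while
island calling stays well powered (~30 tags per 50-bp peak window
against a background of ~0.7).

**What the synthetic tests show, and what they do not.**  Passing
parameter recovery (MLL4 islands at precision/recall ≥ 0.9, dependent
genes ≥ 0.95, element classes ≥ 0.95) demonstrates the pipeline's
internal consistency: the statistical machinery recovers exactly the
structure the generator planted, and calls nothing on null data.  The
generator deliberately omits mappability structure, GC bias, copy-number
variation, fragment-length dispersion, overlapping genes, and broad
domain-shaped (non-rectangular) enrichment; performance on real
libraries depends on those factors and on antibody quality, and is not
established by these tests.

## Known limitations

* Single-end tags only; no paired-end handling.
* No byte-level compatibility with any particular published island
  caller is attempted; the island definition is implemented from first
  principles.
* Promoter windows of adjacent TSSs may overlap each other; the
  mutual-exclusion guarantee applies between classes, not between
  elements of the same class.
* Transcript-level quantification and spliced-alignment awareness are
  out of scope; expression is exon-union RPKM with a fold-change rule,
  not a differential-expression model.
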