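# Methods

This note records the models implemented in `hicscape`, the reasoning
behind the tunable parameters, what the synthetic-study generator does and
does not emulate, and the numerical decisions a maintainer would otherwise
have to reverse-engineer from the code.

## Contact matrices and ICE balancing

Matrices are per-chromosome, symmetric, stored as upper-triangle triplets
at a fixed bin size (0-based half-open bins: bin *k* covers
`[k·r, (k+1)·r)`). Only intrachromosomal analysis is supported; genome-wide
operations iterate chromosomes.

ICE models the observed count as `M_ij = T_ij · b_i · b_j` with a
balanced target `T`. Bins with zero marginal, and bins at or below the
`low_coverage_quantile` (default 0.02) of the positive marginals, are
masked before balancing and stay invalid (NaN bias) downstream — masked
bins are *missing data*, not zeros, and every consumer treats them that
way (this matters: feeding zeros into the arrowhead transform fabricates
one-sided corners at mask edges). The iteration
`b_i ← b_i · s_i / mean(s)` stops when the coefficient of variation of the
corrected marginals drops below `tol` (default 1e-5, cap 200 iterations;
non-convergence returns the best iterate with a warning). The corrected
matrix is rescaled so its mean marginal matches the raw mean, a cosmetic
convention — all downstream statistics are scale-free. At megabase
resolution the pipeline disables the coverage mask
(`low_coverage_quantile=0`): every 1-Mb bin of a usable chromosome is
deeply covered, and a quantile mask would always sacrifice at least one
bin per chromosome and distort the switch denominator.

Note one identifiability caveat: ICE forces uniform marginals, so genuine
marginal structure (chromosome-end effects of the distance decay) is
absorbed into the recovered bias. Bias-recovery accuracy is therefore
assessed on a flat (balanced) target, where the bias is identified up to a
global scale.

## SCC reproducibility

Both maps are smoothed with a `(2h+1)²` mean filter (default `h = 2`),
then for each distance stratum `d` up to `max_distance` (default 5 Mb) the
Pearson correlation `ρ_d` is computed over pixels whose bins are valid in
both maps, and combined with weights `w_d = N_d σ¹_d σ²_d`. The weights
are a transparent stand-in for the variance-stabilized weights of the
published stratum-adjusted method; the stratification and smoothing follow
the same design. Two implementation details: strata are trimmed by `h`
pixels at each end, because clipped smoothing windows there mix in
off-stratum means identically in both maps and fake correlation; and
zero-variance strata are skipped (a map with no variance in any stratum is
rejected as degenerate).

## A/B compartments

Per chromosome, at `compartment_resolution` (default 1 Mb): O/E transform
of the balanced matrix over valid bins → Pearson correlation matrix
(zero-variance columns are masked, not imputed) → eigendecomposition. The
top `n_components` (default 3) eigenvectors are candidates; each is scored
by `|corr(v, gene density)| × eigenvalue` and the winner is sign-flipped
so the correlation with gene density is positive. A > 0, B < 0. The
eigenvalue factor matters: orientation by gene density is reliable, but
*selection* by `|corr|` alone becomes unstable precisely when compartment
switching is heavy — the current state decorrelates from the fixed gene
annotation and a low-eigenvalue noise component can win by chance. The
chosen component index is recorded per chromosome. Chromosomes with fewer
than `min_valid_bins` (10) valid bins are reported entirely invalid with a
warning.

Switch analysis classifies each jointly-valid bin (A→A, A→B, B→A, B→B);
the switch percentage uses the jointly-valid count as denominator and is
symmetric in its arguments. Pattern clustering assigns each bin its sign
string across samples (`BBA` etc.) and orders bins by average-linkage
hierarchical clustering of their PC1 vectors for heatmap rendering.
Concordance genes are selected by locus-midpoint bin membership plus the
sign of the expression log2 fold change; genes absent from the DE table
are reported as skipped rather than silently dropped.

## Contact domains

The arrowhead transform
`A(i,d) = (M(i,i−d) − M(i,i+d)) / (M(i,i−d) + M(i,i+d))` is clipped to
[−1, 1] (smoothed inputs can produce denormal denominators) and is NaN
off-matrix or at zero denominators.

For a candidate `[a, b)` the corner score averages, over pixels
`a ≤ i < j < b`, the *informative* transform terms only: the
downstream view `A(j, j−i)` when its mirror `2j−i` falls at or beyond
`b`, and the upstream view `A(i, j−i)` (negated) when its mirror falls
before `a`. Terms whose mirror stays inside the candidate compare the
domain with itself and carry no boundary information; including them (the
naive full-triangle mean) halves the contrast of a true domain without
reducing noise. For an enrichment-`e` domain on flat background the ideal
score is `(e−1)/(e+1)` (0.5 at the default 3×); a featureless decay
background scores 0, which also makes the caller invariant to global
scaling.

Candidate selection, highest score first:

* score must exceed `max(score_threshold, noise_z · 0.7 · √2 / ℓ)` for an
  ℓ-bin candidate — the second term is a conservative noise floor from
  the fact that |A| ≤ 1 (per-term σ ≲ 0.7 at shallow counts) and the
  score averages ~ℓ²/2 terms, so its null σ is ≲ 0.7·√2/ℓ; defaults
  `score_threshold = 0.3`, `noise_z = 5.5`, `min_domain_bins = 10`,
  `max_domain_bins = 200`;
* at least half the informative terms must be defined (mask/edge rule);
* near-duplicates (both boundaries within `nms_radius = 2` bins of an
  accepted call) are suppressed;
* partial overlap with an accepted call is forbidden; containment either
  way is allowed only at a size ratio ≥ `min_nest_ratio = 2` (marginally
  larger "containers" are ridge artifacts of the contained corner, and
  marginally smaller candidates are its echo), and a nested candidate
  additionally needs ≥ `nested_score_ratio = 0.75` of the enclosing
  score (genuinely nested domains carry extra enrichment of their own).

Boundaries are the deduplicated start/end points with ±5 kb flanks.
Common domains are best-reciprocal matches with > 80 % overlap in *both*
directions (the matching is greedy on the smaller of the two fractions,
each domain pairing at most once). Histone-state classification selects,
per mark, peaks with signal in the top 25 % (ties at the threshold
included; the signal is whatever the BED signal column carries); a domain
is mark-enriched iff it intersects ≥ 1 selected peak, and the single-class
view applies the precedence active (H3K36me3) > heterochromatic (H3K9me3)
> repressed (H3K27me3) while the flag table keeps all three bits.
Gene-in-domain membership is locus-midpoint containment; state-switch
reports use the sample-2 interval of each common pair.

## Loops

Called on the *raw* matrix plus the ICE bias vector. For each tested
pixel (valid bins, separation within `[min_distance, max_distance]` =
[20 kb, 2 Mb]) four local expectations are formed from the balanced
matrix: donut and lower-left with outer half-width `donut_width = 5` and
inner exclusion `peak_width = 2`, plus 3-wide horizontal and vertical
strips. Each neighborhood's enrichment ratio `ΣN/ΣE` is rescaled by
`E(d) · b_i · b_j` to a raw-scale Poisson mean; the observed count is
tested against each, p-values are BH-corrected per neighborhood over all
tested pixels, and a loop pixel must satisfy all four `q < fdr`
(default 0.05) *and* per-neighborhood fold floors (donut ≥ 1.75, others
≥ 1.5) *and* a minimum raw count (`min_observed = 10`). Significant pixels
within `cluster_radius = 15 kb` merge to the maximal-observed
representative. Neighborhood sums come from integral images, so the
caller is O(pixels) rather than O(pixels × window).

Two deliberate deviations from the published donut-filter design are
documented here: BH is global per neighborhood rather than
lambda-chunked; and each Poisson mean is inflated by
`lambda_ucb_z = 2.5` standard errors of its neighborhood ratio (relative
SE estimated as `1/√(raw neighborhood count)`). The inflation compensates
for testing against an *estimated* expectation: with ~10⁶ discrete
Poisson tests per chromosome, plain BH lets an occasional lone 11-count
pixel cascade through even on featureless data, and the upper-confidence
expectation removes exactly that failure mode at a negligible cost in
power (verified on 80 loop-free decay genomes and the planted-loop
recovery sweeps).

Element definitions follow the standard rules: promoter = strand-aware
upstream 2-kb TSS window of an expressed gene (mean FPKM > 1 by default)
overlapping ≥ 1 H3K4me3 peak; enhancer = H3K27ac peak whose edge-to-TSS
gap exceeds 2 kb for *every* annotated gene; insulator = CTCF peak
overlapping neither. The upstream-only promoter window is the literal
reading of "−2 kb window"; a ±2 kb variant is one parameter away
(`promoter_window`). Peak–TSS distance is edge-to-point (0 if a TSS lies
inside the peak) — a midpoint convention would be the other defensible
choice and is not what is implemented. Anchor–element overlap is ≥ 1 bp
of the bin-sized anchor with no padding; anchors are labelled with
priority P > E > I > N and categories are unordered pairs canonicalised
in that order (an enhancer–promoter loop prints as `P-E` whichever anchor
carries which). CTCF-mediated loops default to the "either anchor" mode
('both' is available). Genes looped to enhancers require one anchor on
the enhancer and the other on the gene's promoter element, with loop and
enhancer provenance kept. NDRs are element-peak ∩ ATAC intersections
emitted for external motif tools.

## Expression and survival statistics

Differential expression *is* DESeq2 (pydeseq2): two-group Wald test,
`log2FoldChange` of group 2 vs group 1, BH-adjusted p, flag =
`padj ≤ 0.05 and |log2FC| ≥ 1`. Genes with all-zero counts in both groups
are excluded and listed in `result.attrs['excluded']`. A rank test is not
a usable stand-in here: with 3 + 3 replicates the exact two-sided
rank-sum p can never go below 0.1, so no gene could ever be flagged.

The Wilcoxon rank-sum test enumerates the exact permutation null (with
midranks, so ties are handled) when `n + m ≤ 12`, and otherwise uses the
tie-corrected normal approximation with continuity correction; the two
paths agree within ~0.02 at the boundary. FPKM is
`counts · 10⁹ / (locus length · library size)` — annotated locus length,
no isoform model.

The gene-set score is a single-sample rank-based running sum (ssGSEA
style): genes sorted by expression descending, hits increment
proportionally to `rank_value^weight` (default weight 0.25, rank_value =
N..1), misses decrement uniformly, and the score is the sum of the
running-sum values. This is a documented stand-in for kernel-CDF GSVA;
the stratification contract is preserved exactly: patients split at the
median score, with ties assigned to the *low* group (score ≤ median →
low). Kaplan–Meier curves and the two-group log-rank test come from
lifelines (standard product-limit and O−E/V with 1 df).

## The synthetic study

The generator emulates a two-condition ("primary" vs "metastatic")
multi-omic study. Defaults, chosen once as the desk-scale study
conditions:

* genome 2 × 20 Mb, 5-kb bins (4000 bins/chromosome), 1-Mb compartment
  bins; 10⁶ contacts per chromosome; decay `(1+d)^−1`;
* compartments: alternating A/B blocks of 2–6 Mb; plaid multiplier ×2
  same-label / ×0.5 cross-label, applied only beyond 1 Mb separation —
  the checkerboard is a long-range feature, and a distance-uniform plaid
  would (unrealistically) make every compartment transition look like a
  domain corner at 5 kb; 30 % of megabase bins switch between samples,
  planted as contiguous block runs (B→A first, A→B for any remainder),
  each label keeping ≥ ~30 % of the chromosome so the plaid stays
  resolvable in both samples;
* domains: 10 per chromosome, 100–300 kb, 3× interior enrichment, ≥ 25 kb
  gaps, states cycling active/heterochromatic/repressed; one nested
  sub-domain inside the largest domain per chromosome (its own 3× on top
  of the parent); in the metastatic sample 20 % of inactive domains split
  in two (left half active) and a disjoint 20 % keep their span but
  switch inactive→active;
* loops: per chromosome 5 common, 3 primary-specific, 6
  metastatic-specific enhancer–promoter pairs; 2×2-pixel 6× focal peaks
  at 30–60 kb separation (the canonical enhancer–promoter range, and the
  range where a 6× focal peak at this depth carries enough counts for
  single-pixel Poisson detection); anchors keep a donut-width margin from
  domain boundaries so no planted peak straddles a sharp background step;
  the enhancer peak spans both block bins and the promoter TSS sits just
  past the block's internal bin boundary, so whichever block pixel a
  caller reports overlaps the planted elements;
* per-bin coverage bias log-uniform on [0.65, 1.55], the spread of
  retained bins after the usual low-coverage filtering (wider spreads
  leave focal peaks at unlucky anchor pairs with too few raw counts to
  ever reach significance at this depth);
* tracks: per state mark, three high-signal foreground peaks per matching
  domain and exactly three low-signal background peaks per foreground
  peak, with separated signal ranges — the top-25 % selection then
  recovers the foreground deterministically; H3K4me3 at every
  expressed-gene TSS; CTCF on domain boundaries and loop anchors at rate
  0.8 each plus background; ATAC covering every planted NDR;
* expression: negative-binomial counts (dispersion 0.1, 3 replicates per
  condition), baseline log-mean higher for A-compartment genes; genes
  looped to metastatic-specific enhancers +2 log2FC, to primary-specific
  enhancers −2, in state-switch domains +2, in switched compartment bins
  ±2 by direction; patients (n = 176) carry the planted up-set at ×4 in a
  latent high-risk half, with exponential survival at hazard ratio 2 and
  administrative censoring at 2000 days.

Everything is deterministic given the seed. Hi-C pixel noise is Poisson
(not negative-binomial): no overdispersion knob yet. Other features of
real data the generator does not emulate: translocations and copy-number
structure, isoform-level expression, mappability-correlated (rather than
independent) bias, inter-chromosomal contacts, and hg19-like annotation
density. Passing the recovery tests therefore demonstrates correctness of
the algorithms under the stated generative model, not performance on real
tissue data.

## Problem sizes and runtime

The test suite and the acceptance script run everything at the default
desk scale: 2 × 20 Mb genomes for recovery tests (~1 min for a full
pipeline run), 200-bin constructed matrices for ICE, 500-bin genomes ×
20 replicate pairs for SCC separation, 1000-bin decay genomes × 20 seeds
for the loop false-positive control, and 100 seeded cohorts of 176
patients for survival power. The full suite completes in roughly ten
minutes on one CPU.

## Known limitations

* The corner-score domain caller is a deterministic simplification of the
  published arrowhead corner statistics (no variance/sign matrices); its
  parameters were calibrated on the generative model above and should be
  re-examined before use on deeply sequenced real data.
* SCC weights are not variance-stabilized; absolute SCC values are
  comparable within this package, not against HiCRep outputs.
* The gene-set score is ssGSEA-style, not kernel-CDF GSVA; score
  magnitudes differ from GSVA even though the median-split stratification
  behaves the same.
* Compartment calling needs a resolvable plaid: chromosomes dominated by
  a single compartment return an eigenvector that mostly reflects noise
  (the generator explicitly avoids creating such chromosomes).
* All loop statistics are intrachromosomal; `.hic`/cooler binary formats
  are not parsed (triplet TSV plus chrom.sizes only).
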