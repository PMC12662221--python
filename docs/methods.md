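# Methods

This note documents the statistical procedures, the synthetic-data models
behind the test suite, the parameter defaults and the reasoning where the
design was genuinely open.

## Coordinate conventions

All genomic coordinates are 0-based, half-open (BED convention). Two
intervals overlap iff `max(starts) < min(ends)`; touching intervals are
disjoint; abutting intervals merge at `gap=0`, matching `bedtools merge`.
Gene loci are windows of total width `window_kb` (default 300 kb) centered
on the TSS, strand-agnostic for assignment; locus-report offsets are
TSS-to-region-center distances signed positive in the direction of
transcription.

## Differential accessibility and the regulome

Counts are pooled (summed) over replicates per condition. Each induced
condition is compared with the baseline after scaling by **median-of-ratios
size factors**: with pooled vectors *t* and *b*, the reference is
`sqrt(t_r * b_r)` per region and `s_t = median(t_r / ref_r)` (and
symmetrically for *b*), normalized so `s_t * s_b = 1`. Total-count
(per-million) scaling is deliberately not used for testing: when a large
fraction of counted regions responds — which is exactly the regime the
synthetic experiments plant — total counts are composition-biased and shift
every log-fold-change by the library-composition ratio. Median-of-ratios is
the estimator the DESeq family of differential tools uses for the same
reason. Plain per-million scaling remains available as
`AccessibilityMatrix.cpm()`.

The fold change is `log2(t/s_t + c) − log2(b/s_b + c)` with pseudocount
`c = 0.5` (unstated upstream; 0.5 is the common Haldane-style choice, and
the difference-of-logs form keeps antisymmetry exact in floating point).
The p-value is a two-sided exact binomial test: conditional on `t + b`, the
treatment count is Binomial(n, `s_t/(s_t+s_b)`) under no change. This is a
deliberately simple exact stand-in for a negative-binomial GLM; it is
anti-conservative for overdispersed data, which is why regulome *selection*
defaults to the fold-change rule (`max |log2FC| >= 1` over induced
conditions) with the FDR gate (`require_q=True`, BH q ≤ 0.05 per
comparison) exposed as an option rather than imposed — the two published
descriptions of the selection (two-fold rule vs FDR rule) differ, and both
are available.

### GRE classes

Rules are evaluated in a fixed order (DIND first, since its reference
pattern is a strict subset of no other class but its response overlaps
TE-GRE): DIND requires a positive response at ≥ 1 low-dose *and* ≥ 1
high-dose condition and closed ESC/TSC references; TE-GRE opens with a TSC-
open/ESC-closed pattern; ESC-GRE closes with ESC-open/TSC-closed; SC-GRE
closes with both references open; anything else is unclassified. Openness
is binarized at a threshold `tau` (inclusive ≥); `tau="auto"` applies Otsu
to the pooled log1p replicate-mean signal of the two reference conditions —
the references are designed to be bimodal (open vs closed), which is Otsu's
model.

The clustering route z-scores each region's profile, uses
1 − Pearson correlation as distance and Ward (D2) agglomeration, cuts at
k = 4, and labels each cluster with the class whose archetype profile (a
0/1 openness pattern over the design roles, with induced columns of
dose-dependent classes scaled by dose) best correlates with the cluster
centroid; ties break by the priority TE > ESC > SC > DIND. Constant rows
are assigned a zero-correlation convention with a logged warning.

### Binding, dose skew and motifs

CEBPa binding is a ≥ 1 bp overlap with any ChIP peak. Differential binding
between dose fractions discards sites with mean count < 20 before testing
(the filter is absolute: a discarded site can never be reported), then
applies the exact binomial test with total-count library ratios and BH.
Motif enrichment builds one 2×2 table per motif (foreground hit/miss vs
background hit/miss) and computes a two-sided Fisher exact p by summing
hypergeometric probabilities of all tables at most as likely as the
observed one, with a relative tie tolerance of 1e-7 (the convention shared
with standard implementations); odds ratios receive the Haldane +0.5
correction only when a cell is zero; BH runs across motifs.

## Enhancer states against embryo tracks

A region is accessible at a stage iff it overlaps an ATAC peak under the
replicate rule, default `"all"` (every replicate) — peak presence in both
biological replicates is the conservative reading of replicated embryo
tracks; `"any"` is available. "Accessible in early embryos" means
accessible at 4C *or* 8C. H3K27ac is accepted from any provided H3K27ac
set (the stage-specific alternative is not encoded because stage-matched
acetylation tracks are rarely all available). The activated/primed/standby
partition is exhaustive and exclusive by construction. Early-opening
regions are universe members with *no* 2C overlap in any replicate (an
"any" rule here is the conservative direction: one replicate's peak is
enough to disqualify a region from being "closed at 2C") that are
accessible at 4C/8C. Class enrichment among early-opening regions uses the
same Fisher machinery with one class-vs-rest table per class.

## Resampled cluster similarity

Both expression matrices are restricted to shared genes, log1p-transformed,
per-gene centered/scaled on the concatenation, and projected on the top 15
principal components (deterministic sign: largest-magnitude loading
positive). For reference cluster Y, `N = 2|Y|` and the neighbor set is the
N non-Y cells nearest Y's *centroid* (Euclidean; ties by stable cell
order); similarity of query cluster X is `|X ∩ neighbors(Y)| / |X|`. The
published description leaves three details open — neighbors of a centroid
vs per-cell pooling, exclusion of Y's own cells, and the denominator —
and the choices here (centroid, exclude Y, divide by |X|) are the simplest
set that keeps the statistic in [0, 1] and symmetric in cluster size. The
per-cell reading is available as `neighbor_mode="per_cell"` (union of each
Y cell's 2 nearest non-Y cells, the same 2|Y| neighbor budget). Each
of the 10 iterations subsamples every query cluster to ≤ 50 cells without
replacement and recomputes the embedding. Anchor-based integration is out
of scope; the statistic accepts any externally supplied embedding via
`EmbeddedCellSet`.

## 3D nuclei

Smoothing is per-slice 2D (size 9, σ = 5 by default), a truncated
renormalized kernel with reflective ("symmetric") boundaries. One Otsu
threshold (256 bins) per stack; mask is strictly `> threshold`. Per-slice
components are 8-connected; components in adjacent slices are linked when
`|A∩B| / min(|A|,|B|) ≥ 0.5`, resolved greedily by decreasing overlap with
deterministic tie-breaks, each component linking at most once per
direction; chains form nuclei and objects under 50 voxels are discarded.
Intensities are measured on the raw channels — smoothing exists only to
build the mask. The whole module is deterministic.

**Smoothing scale vs resolution.** The σ = 5 default matches
full-resolution micrographs in which a nucleus spans on the order of a
hundred pixels. The synthetic stacks are generated at coarse resolution
(radius 6–9 voxels) to keep test fixtures small; at that scale a σ = 5
blur widens the Otsu mask by ~2 voxels beyond the true boundary and biases
per-nucleus means by ~20% regardless of nucleus size. Tests and the
acceptance script therefore segment synthetic stacks with σ = 1.0 — the
study-scale kernel scaled by the same resolution ratio as the images —
which recovers planted counts exactly and means to well within 2%.

## Synthetic-data models

All generators are pure functions of their arguments including a mandatory
seed, and always emit the planted truth.

**Regulome counts.** Log-normal signal: per-region baseline mean (open ≈ 200
or closed ≈ 20 counts per replicate, jittered ±0.5 log2 units), class
effects of ±1.5 log2 units at low dose (high dose scaled by
`dose_ratio = 1.3`, except DIND which is dose-independent), multiplicative
log-normal noise (`noise_sd = 0.25` log2 units), Poisson sampling to
integer counts. With `noise_sd = 0` the exact means are emitted without
Poisson sampling so planted effects are recoverable exactly. The design has
two replicates of baseline, 48 h/72 h × low/high induced fractions and
ESC/TSC references. ChIP peaks cover 60% of TE-GREs and 80% of DIND sites
(binding concentrates on the opening classes) plus decoys. Defaults are
desk-sized (200 per class + 400 background, ~16% of the count scale of a
real experiment). What this model omits: overdispersion beyond Poisson,
GC/width biases, peak-boundary uncertainty — passing tests show the
thresholds and rules behave, not that the binomial p-values are calibrated
for real ATAC-seq.

**Embryo tracks.** Non-standby regions get an ATAC peak (400 bp, center
jittered ≤ `jitter_bp` with guaranteed ≥ 1 bp overlap) in both replicates
of 4C, 8C, or both; occasionally a single-replicate-only peak at the other
stage exercises the replicate rule; activated regions also get an H3K27ac
peak; 2C tracks and decoy peaks live on a separate chromosome band.

**Clustered expression.** Cells are log-normal around cluster centroids.
Each cluster identity owns a 20-gene signature block whose amplitude is
analytically inflated so that the centroid separation *after* the per-gene
standardization of the embedding equals the requested `separation` (in
per-gene-sigma units) — without the correction the standardization absorbs
most of a single-gene signature and "separation 10" would mean 2–3 in the
embedding. Reference (embryo-stage) clusters default to 25 cells each,
realistic for preimplantation datasets where one stage contributes tens of
cells, and each stage has one matched query cluster sharing its centroid.

**Nuclei stacks.** Spheres with uniform interior intensity per channel,
pairwise center separation ≥ `r_i + r_j + margin` (margin 10), background 0
plus clipped Gaussian noise (sd 2). The per-nucleus (A, B) intensity pairs
are built from exactly standardized orthogonalized variates, so the
*sample* Pearson correlation of the planted means equals `corr` exactly for
n ≥ 3; `corr = 1` yields exactly collinear means.

## Numerical choices

- BH q-values via `scipy.stats.false_discovery_control`; tests pin them to
  the textbook estimator.
- Fisher p via explicit hypergeometric enumeration
  (`fisher_pvalues_for_margins`), cross-checked in tests against
  `scipy.stats.fisher_exact` and a rational-arithmetic (Fraction)
  enumeration oracle to 1e-9 for all tables with total ≤ 40.
- Ward linkage heights are cross-checked against a hand-rolled
  Lance–Williams agglomeration on small instances, and are monotone.
- PCA uses the full (deterministic) SVD solver; component signs follow the
  largest-|loading|-positive convention.
- Problem sizes in tests and the acceptance script (1,200 regions, 30
  enhancer regions, ~300 cells, 12–50 nuclei) are the package's desk-scale
  defaults; real datasets are one to two orders of magnitude larger on
  every axis.

## Known limitations

- The exact binomial test underestimates biological variability between
  replicates (it pools them); use the FDR gate plus an external
  negative-binomial tool when calibrated error rates matter.
- The hierarchical-clustering route assumes k = 4 biologically distinct
  profiles; with fewer real classes the archetype labeling will reuse
  class labels across clusters.
- The similarity statistic depends on cluster sizes through `N = 2|Y|`;
  with reference clusters larger than half the dataset the neighbor set
  saturates and the statistic loses discrimination.
- Watershed splitting is not implemented: touching nuclei closer than the
  smoothing scale merge into one object.
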