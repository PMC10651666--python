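# Methods

This note documents the statistical models, the synthetic-data
generators, the numerical choices and the known limitations of
`myoaging`.

## Scientific setting

The package analyzes how skeletal-muscle gene expression changes with
age in men and women, asked as three questions: (i) which genes change
with age in each sex (old vs young, within sex); (ii) how much of that
change is shared between the sexes versus sex-specific; and (iii) for
genes called in only one sex, does the other sex move in the same
direction with a smaller magnitude (a quantitative difference) or in a
different direction (a qualitative one)? A companion image-analysis
component quantifies muscle fiber types and fiber sizes from two-channel
immunofluorescence sections (MYH7 marking slow/type-1 fiber interiors in
green, dystrophin marking the sarcolemmal boundary of every fiber in
red).

## Count simulation

`simulate.simulate_counts` draws a gene x sample matrix over four groups
(young/old x male/female; default sizes 13/28 males and 13/26 females,
80 samples). Genes belong to four blocks:

* **shared** — one true log2 fold change (log2FC), identical in both
  sexes;
* **male_block** — a dominant male effect; the female true log2FC is
  `a_m` times the male value (same sign);
* **female_block** — the mirror image with factor `a_f`;
* **null** — no age effect.

Dominant-effect magnitudes are uniform on `lfc_magnitude_range`
(default [0.5, 2.0]) with a random sign (p = 1/2 each), baselines are
log-uniform on [20, 2000] expected counts, and counts are negative
binomial with variance mu + phi * mu^2 (phi = 0.05 by default; phi = 0
degenerates to Poisson). Per-sample library-size factors, log-uniform on
[0.7, 1.4], multiply every mean so that normalization is exercised
non-trivially. Defaults `a_m = 0.40` and `a_f = 0.52` mirror the
cross-sex fold-change slopes observed in two-sex muscle-aging cohorts
(female-on-male slope ~0.4 within male-specific genes, ~1.9 within
female-specific ones, i.e. 1/1.9 ~ 0.52 in the male direction); block
sizes default to 2,000 / 700 / 2,600 / 7,000, keeping the female-
dominant asymmetry of such cohorts. All randomness flows from a single
integer seed through `numpy.random.default_rng`, so outputs are
bit-reproducible.

What the generator deliberately omits: GC/length biases, batch effects,
gene-gene correlation, outlier samples and read-level noise. Passing the
simulation-bound tests therefore demonstrates the pipeline's correctness
and calibration under a clean NB model, not robustness to every artifact
of real RNA-seq.

The probe-level generator (`simulate_probe_table`) wraps the same
gene-level truth in a microarray-style error model: each probe reports
`lfc + N(0, sigma)` (sigma = 0.25 by default) and the two-sided normal
p-value of the corresponding z-score, so null-gene probes yield uniform
p-values — which pins down the type-I behavior of everything built on
top.

## Normalization and the differential-expression test

Size factors use the median-of-ratios construction: reference genes are
those with nonzero counts in every sample, the pseudo-reference is the
per-gene geometric mean, and a sample's factor is the median ratio
against it, rescaled so the factors' geometric mean is exactly 1 (the
rescaling cancels in all downstream ratios; a test cross-checks the
estimator against pyDESeq2 to machine precision up to that constant).

The per-gene test contrasts old vs young normalized means within one
sex. With group means m_y, m_o over n_y, n_o samples:

* log2FC = log2((m_o + c) / (m_y + c)), pseudo-count c = 0.5 normalized
  counts (keeps sparse genes finite; genes with all-zero counts report
  log2FC 0, p 1);
* gene-wise dispersion by method of moments from the pooled
  within-group variance, phi = (s^2_pooled − m_bar) / m_bar^2 with
  m_bar = (m_y + m_o)/2, floored at 1e-8;
* delta-method standard error of the log2 contrast under
  Var(count) = mu + phi mu^2;
* Wald statistic log2FC / SE referred to a **t distribution with
  n_y + n_o − 2 degrees of freedom**. The t reference (rather than the
  normal) absorbs the variability of the moments-estimated dispersion at
  biopsy-study group sizes; with it, the empirical type-I error on
  10,000 null genes sits inside the binomial band at both alpha = 0.01
  and 0.05, whereas the normal reference is anticonservative.

DEGs are called at raw p < 0.01 (equivalently −log10 p > 2).
Benjamini–Hochberg adjusted p-values are reported alongside but never
used for calls, matching common practice in the cohorts this pipeline
emulates. No fold-change shrinkage, covariate adjustment or independent
filtering is applied.

PCA operates on centered log2(normalized count + 1) restricted to the
5,000 highest-variance genes by default. "Most regulated" is ambiguous
between variance- and significance-based ranking; variance is the
default and a precomputed score ranking can be supplied instead
(`top_by="scores"`).

## Partition and concordance

At a common alpha the gene universe splits into shared (significant in
both sexes), male-specific, female-specific and neither; the four sets
are disjoint and exhaustive by construction. For any gene set, the
concordance statistics over the paired (male log2FC, female log2FC)
values are:

* **pct_same_direction** — the percentage of pairs with equal signs
  among pairs where both values are nonzero (zero-valued pairs carry no
  direction; they are counted separately as `n_zero`);
* Pearson R;
* the OLS regression of female on male log2FC **with intercept** —
  the slope m reads as the cross-sex magnitude ratio — and the
  two-sided p of the slope.

Two biases of this convention are inherited deliberately, because they
belong to the method being reproduced rather than to its best possible
version: OLS attenuates the slope when x is noisy, and conditioning on
significance in one sex selects for over-estimated effects in that sex.
Together they push the fitted slope within sex-specific sets below the
generating attenuation (e.g. ~0.25 measured against a_m = 0.40 in the
default scenario); the generating value is recovered exactly when
regressing the noiseless truth, which a test asserts.

Gene-list restricted concordance matches symbols case-insensitively,
logs (never fails on) unmatched entries, and exposes three selections:
all listed genes, listed DEGs of either sex, or listed DEGs of exactly
one sex — the reading of "genes selected by a GO term" differs between
figures in this literature, so all three are available. The ranked
profile sorts listed genes by the two sexes' average −log10 p,
descending, with lexicographic tie-break.

## Probe collapse and cohort replication

Microarray cohorts arrive as per-probe (gene, probe, log2FC, p) tables,
one per sex. Collapse rule, per gene: if any probe has p < alpha, the
gene value is the arithmetic mean of −log10 p and of log2FC over the
significant probes only (`significant_only`); otherwise the mean over
all probes (`all_probes`); single-probe genes pass through (`single`).
The logarithm base is 10 throughout, fixed by the DEG rule
−log10 p > 2. Collapse is idempotent on gene-level tables, and adding a
significant probe can never demote a gene from `significant_only`.

When a cohort is supplied as a probe x sample log2-expression matrix,
per-probe statistics are Welch's t (old vs young) with the mean
difference as log2FC; how the original cohort analyses computed their
probe statistics is generally unstated, so this default is documented
and pluggable rather than claimed as a replication of any specific
pipeline. The replication report re-runs partition + concordance per
cohort and adds the female excess 100 (n_f − n_m) / n_m.

## Histology

`render_section` builds a disc of tissue tiled by convex fiber
polygons: blue-noise seed points (dart throwing, minimum spacing 0.6 of
the mean fiber diameter) are Lloyd-relaxed twice, their Voronoi cells
are clipped to the disc, and each cell is offset inward (mitre join) by
half the boundary gap (default 3 px total), guaranteeing disjoint convex
polygons with a >= 2 px gap. The green channel paints type-1 interiors,
the red channel paints the entire non-interior tissue — the dystrophin
boundary network; both sit on a background of 20 with foregrounds of 200
and additive Gaussian noise (sigma = 15, 8-bit clipping). Pixel pitch
defaults to 0.5 um/px and is recorded with the truth.

Quantification mirrors the ImageJ-style workflow: Otsu (or fixed)
thresholds per channel; slow fibers are 8-connected components of the
green mask; fast fibers come from filling the holes of the red boundary
network, subtracting the network and the slow area ("filled" mode — the
raw red-threshold subtraction is also exposed as "raw" mode, since
published descriptions do not distinguish the two); components under
50 px^2 are discarded as specks. Fixed thresholds are required for
between-batch intensity comparisons (`mean_tissue_intensity`), which
average a channel over its pixels at or above the tissue threshold.

The minimal Feret diameter — the preferred size read-out because it is
least sensitive to oblique sectioning — is the minimum caliper width of
the convex hull, computed exactly by the rotating-calipers property that
the minimal width is attained flush against a hull edge. Pixel masks are
measured on the corner points of their boundary pixels, so an
axis-aligned square of side s measures exactly s and a disc of radius r
measures 2r within one pixel. Degenerate (collinear) inputs return a
zero width rather than failing. Sections with fewer than 70 fibers fail
QC, following the exclusion rule standard in muscle morphometry.

Verified recovery at the defaults (25 seeds, 300 fibers): type-1
percentage within +/-2 points of truth (exactly 0 in all observed
seeds), per-type mean minimal Feret within +/-3% of the truth polygons'
analytic value (observed bias ~ +1.3%, from the half-pixel footprint of
rasterized polygons), type-call accuracy 100% at default noise. The
renderer does not model uneven illumination, channel bleed-through or
z-stack projection; segmentation accuracy on real micrographs will be
lower than on these mosaics.

## Problem sizes and runtime choices

The standing benchmark scenarios use 10,000-12,300 genes x 80 samples
with 25 replicates, and 300-fiber sections over 25 seeds — sizes at
which every statistic of interest is stable (replicate SD of the female
excess ~1 point, SEM ~0.2) while a full test run stays around a minute.
The acceptance script (below the repository root at
`scripts/acceptance.py`) recomputes all headline numbers from scratch at
exactly these sizes.

## Known limitations

* The DE test is a transparent NB Wald, not a DESeq2 clone: no
  dispersion shrinkage across genes, no outlier refitting, no lfc
  shrinkage. Absolute DEG counts on real data will differ from
  DESeq2's, although the cross-sex comparisons are symmetric in the
  sexes by construction.
* Under high power, mildly attenuated cross-sex effects are themselves
  detected in both sexes, which enlarges the shared set and compresses
  the female DEG excess relative to lower-powered studies; the excess
  measured in the asymmetric benchmark (~24%) sits slightly below the
  smallest excess printed in the replication cohorts (26%).
* Gene identifiers are opaque strings; no annotation, orthology or
  GO-term retrieval is performed — gene lists are user-supplied files.
* The histology ground truth is a convex mosaic; real fiber
  cross-sections can be concave, and real sections contain freeze
  artifacts and connective tissue that the generator omits.
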