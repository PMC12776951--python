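# Methods

This note documents the models and procedures implemented in `spikemap`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical conventions chosen where the design was open.

## Coordinate and data conventions

All coordinates are microns. The apical–basal axis of the spike is the y
axis with the base at minimal y; every axial routine accepts a
`flip_axis` flag for sections mounted the other way. Cell tables are
pandas DataFrames indexed by `cell_id`; count matrices are `AnnData`
objects with raw integer counts in `X`, blank barcodes flagged in
`var["is_blank"]`, and two derived layers after normalization:
`norm_counts` (linear, total-scaled) and `lognorm` (log1p of the former).
Gene names match exactly and case-sensitively; blanks are recognized by a
configurable name prefix (default `Blank`).

## Geometry

Transcript-to-cell assignment is a boundary-inclusive point-in-polygon
join (shapely STRtree, `covered_by`). Segmentation polygons occasionally
overlap; a transcript inside several cells goes to the cell with the
nearest centroid — a deterministic tie-break that keeps re-aggregation
exact. Cell volume is polygon area × section thickness (default 10 µm,
the cryosection thickness); the centre is the polygon centroid. ROI
selection keeps cells whose centre lies inside or on the ROI boundary.

## Quality control

* Thresholds: keep cells with non-blank total ≥ 25 counts AND volume
  ≥ 500 µm³. The keeps are boundary-inclusive because the exclusion rules
  are stated as strict ("<25", "<500 µm³").
* Blank rate: per-cell fraction = blank counts / all counts including
  blanks; the summary is the mean of per-cell fractions (×100), excluding
  zero-detection cells (for which the fraction is undefined); a pooled
  variant is available. Conditional on a cell's total, blank counts are
  binomial, so this estimator is unbiased for the generating rate.
* Cross-hybridization: (mean probe counts/cell) / (mean per-blank-gene
  counts/cell); an all-zero blank matrix yields a flagged infinite ratio.
* Blank genes are dropped from all matrices after QC.

## Normalization, integration, clustering

Normalization is per sample (before integration): each cell scaled to the
median of per-cell totals, then log1p. The inverse-log1p row sums equal
the target to 1e-6 relative — a conservation property the tests assert.

Integration stacks the normalized samples, removes additive batch effects
with ComBat on the lognorm layer, and embeds with PCA (d = 30 by default,
clipped to the panel size). A single sample degrades to plain PCA. The
embedding feeds a kNN graph (k = 15) and Leiden community detection at
resolution 1.0 (igraph backend, 2 iterations, seeded); ED ids are
relabelled by descending size. Determinism given the seed, and invariance
of the partition to cell order, are tested.

Prevalence: an ED counts towards a sample's domain number when its share
of that sample's cells is ≥ 0.5% (inclusive at exactly 0.5%); the global
labeling is never altered.

Marker ranking fits one one-vs-rest L2 logistic regression per ED
(C = 1.0, lbfgs, 200 iterations) on the lognorm layer; the score of a gene
is its coefficient, ties broken by gene name, EDs with < 2 cells excluded
with a warning. The enrichment call is `score > mean + 2·SD` within each
ED's score distribution over genes (sample SD); an alternative axis — per
gene across ED mean expressions — is exposed as
`call_enriched_per_gene` since either reading of "+2 SD" is defensible;
the per-ED-scores variant is the default.

## Axis statistics

* Transect: equal-width bins over the realized y range of the ROI cells
  (default 30), bin 1 basal; per-bin means use the lognorm layer (what a
  profile plot shows). Empty bins report count 0 and NaN means.
* Basal:central ratio: pooled per-cell mean over bins 1–10 divided by
  bins 11–30 — cells pooled, not a mean of bin means, which keeps the
  statistic insensitive to unequal bin occupancy. It is computed on the
  linear `norm_counts` layer ("mean counts per cell" on a log scale would
  compress any fold); raw-count and log-scale variants are one keyword
  away.
* Co-expression is binarized on raw detections (count ≥ 1), per ED, with
  all cells of the ED as denominator; only-A + only-B + both + neither
  sums to 100%.
* Group PCA: group × gene means over member cells (lognorm layer), genes
  kept when any group mean exceeds 0.30 (strict), per-gene z-scores across
  groups (sample SD; constant genes become zero columns), SVD-based PCA.
  Scores are sign-oriented so Spearman ρ(PC1, position) ≥ 0 (and PC2
  likewise when its correlation is nonzero), mirroring the score inversion
  used to put basal groups at the low end of the axis; loadings are
  reported in both the raw and the score-aligned orientation because
  published loading signs usually refer to the pre-inversion axis. The
  Spearman p uses the t-approximation with n−2 df: with only 13 groups the
  asymptotic normal is inaccurate and exact enumeration unnecessary; an
  exact variant exists in scipy if wanted. For ρ = 0.68, n = 13 this gives
  p = 0.0105.
* Ridge sizes: cells per group for listed basal (default positions 1–4)
  and central (8–11) sets; mean and sample SD (n−1); a single group
  reports SD as NaN.
* Pseudobulk: per-gene sums of normalized counts over a cell subset;
  concordance with a bulk TPM reference is Spearman over the gene
  intersection (≥ 3 genes, average ranks for ties).

## The synthetic spike

The generator emulates the *statistical* structure the analysis assumes,
not the tissue's appearance. Geometry: 10 µm square cell tiles; a central
column (vasculature innermost, rachis around it) spanning 13 phytomer
bands of 50 µm; at each band an AM block and an adjacent LR block on
alternating flanks. LR sizes follow a fixed per-position profile
(53, 36, 25, 16, … 12), making basal ridges large and variable
(LR1–4: 32.5 cells on average) and central ridges small and uniform
(LR8–11: 12.5) before QC.

Counts: Poisson with mean = domain program rate × lognormal size factor
(σ = 0.35, unit mean); a Gamma–Poisson (negative binomial) option adds
overdispersion. Programs are rescaled once so the expected mean total per
normal cell equals `mean_total_counts` (default 115, the centre of the
77.9–152.4 counts/cell range of real samples). Defaults per domain: eight
uniform markers at 7 counts/cell (0.25 elsewhere), twenty shared
housekeeping genes at 2.5, six axial genes per flank tissue at 0.8, the
reciprocal gradient pair VRT2 (rachis, 1.2) and SEP1-4 (AM, 1.2), and a
cross-hybridizing control probe whose realized mean is ~0.20 counts/cell,
about 10-fold over blanks.

Gradients are log-linear in y. A gene's `fold` is defined operationally as
the expected pooled basal-third : upper-two-thirds ratio of the transect
analysis, and the slope is calibrated numerically against the realized
cell layout — baseline expression in other domains and the basal-heavy LR
profile dilute the pooled ratio, so a closed-form uniform-density slope
would under-deliver the designed fold. The misexpression genotype flattens
the VRT2 gradient (fold 1) and adds a uniform ectopic VRT2 rate (1.0) in
AM and LR, reproducing loss of basal restriction.

Blanks: per cell, total blank rate = real rate × r/(1−r) split over 15
blank genes (r = 0.0028), which makes the expected blank fraction of all
detections exactly r. Artifacts: 3 µm tiles (volume 90 µm³, below the 500
µm³ cut) placed on the empty flank of each band, drawn binomially so they
form ~5% of objects. Low-count cells: a 5% subset with size factors scaled
by 0.1 (≈ 11 counts/cell, below the count filter).

The default axial-gene strength (rate 0.8, pooled fold 2.0) is deliberately
weak at single-cell level: it leaves the AM and LR domains as single Leiden
communities at resolution 1.0, which the generator's separability contract
(clustering ARI ≥ 0.8 and full designed-marker recovery under the +2 SD
rule) requires — strong within-domain axial structure splits the AM
cluster, and one-vs-rest regression then shifts weight from shared markers
onto the axial genes. Group-level axis analyses that need an unambiguous
monotone program use `axial_program_spec` (axial rates 4.0, fold 3.0),
where PC1 recovers the axis with ρ ≥ 0.95.

The synthetic bulk reference is the program mixture's expected abundance
with lognormal noise (σ = 0.7) scaled to TPM; the noise level puts the
rank concordance of an in-silico dissection against it in the mid-0.6
range typical of imaging-panel versus bulk comparisons.

Everything is deterministic given the spec and seed (a single
`SeedSequence` split across layout and counts); `generate_dataset` writes
byte-identical bundles on re-run and a manifest of seeds and spec hashes.

### What the generator does not emulate

Optical decoding errors beyond the blank-rate abstraction, segmentation
boundary errors (polygons never overlap), z-stack effects, per-gene
dispersion estimated from real data (Poisson by default), stage-dependent
tissue growth (all stages share one geometry), curved or tapering spikes,
and any image-level signal. Passing recovery tests therefore demonstrates
correctness of the statistics under the stated noise model, not robustness
to every failure mode of real segmentation.

## Problem sizes in tests and the acceptance script

Default samples carry ~950 real cells (13 positions); the 8-sample bundle
~7,600 cells — enough for the clustering and enrichment contracts. The
basal:central gradient checks run on 8× spikes (~7,600 cells each): the
pooled ratio's sampling SD is ≈ 8% of its value at default size and ≈ 4%
at 8×, and the generator's own recovery example stipulates at least 2,000
cells. Marker-recovery replication uses ten independent 2-sample bundles.

## Known limitations

* ComBat (location/scale) stands in for panel-level integration; it
  corrects additive batch shifts well but not nonlinear batch distortions.
* The +2 SD enrichment rule is sensitive to coefficient heterogeneity
  within an ED: a few dominant genes can push the threshold above genuine
  markers. The per-gene variant is provided for that situation.
* The t-approximation p-value for Spearman ρ is approximate for n = 13;
  it matches the exact value to the printed precision in the regimes used
  here.
* `domain_prevalence` reports per-sample counts only; it never reassigns
  or removes cells from rare domains.
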