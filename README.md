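# spikemap

Downstream analysis of imaging-based (MERFISH/MERSCOPE-style) spatial
transcriptomics of developing grass inflorescences, built around the wheat
spike: per-cell quality control of cell-by-gene matrices, expression-domain
(ED) clustering with marker enrichment, and the spatial statistics that
describe patterning along the apical–basal axis — transect gradients,
binarized co-expression, group-wise PCA over ordered meristem positions, and
in-silico pseudobulk dissection. A synthetic spike generator with full ground
truth makes every stage testable end to end.

It is written for researchers analysing MERSCOPE-like exports (cell metadata,
cell-by-gene counts, detected transcripts, boundary polygons, ROI polygons)
from plant tissue sections, and for anyone who needs a reproducible,
well-tested reference implementation of this analysis style.

## The analysis in brief

* **Geometry.** Detected transcripts are assigned to segmented cells by a
  boundary-inclusive point-in-polygon spatial join (overlaps resolved to the
  nearest centroid); cell volume is the 2D segmented area × 10 µm section
  thickness.
* **QC.** Cells with fewer than 25 transcripts or volume below 500 µm³ are
  removed (boundary-inclusive keeps). The false-detection rate is estimated
  from "blank" barcodes — codebook entries with no probes — as the mean
  per-cell blank fraction of all detections. Homoeolog cross-hybridization is
  quantified as the fold of a control probe's mean counts/cell over the mean
  per-blank-gene counts/cell.
* **Domains.** Per-sample median total-count normalization and log1p, batch
  correction across samples, PCA embedding, Leiden clustering at resolution
  1.0 on a kNN graph (k = 15). Domains under 0.5% of a sample's cells are
  excluded from that sample's domain count. Markers are ranked per ED by
  one-vs-rest L2 logistic regression; a gene is *enriched* in an ED when its
  coefficient exceeds that ED's mean + 2 SD over genes.
* **Axis statistics.** ROI cells are split into 30 equal-width transverse
  bins along y (bin 1 basal); the basal:central ratio of a gene is the pooled
  per-cell mean over bins 1–10 divided by bins 11–30. Co-expression is
  binarized on raw detections (count ≥ 1) and tabulated per ED. For the 13
  ordered axillary-meristem (AM) and leaf-ridge (LR) groups, normalized
  expression is averaged per group, genes filtered at a 0.30 max-group-mean,
  z-standardized and decomposed by PCA; PC1 scores are oriented so
  Spearman ρ(PC1, position) ≥ 0, with the two-sided p from the
  t-approximation, t = ρ√((n−2)/(1−ρ²)) on n−2 df. Pseudobulk sums
  normalized counts over an ROI and is compared to a bulk TPM reference by
  Spearman rank.
* **Synthetic spike.** A cartoon inflorescence: rachis and vasculature
  columns spanning the axis, AM + LR clusters at 13 phytomer positions on
  alternating flanks; Poisson counts from per-domain gene programs with
  lognormal size factors; reciprocal log-linear gradients (a basal-high,
  rachis-restricted *VRT2*-like gene at a designed pooled 3.46-fold, and an
  apical-high, spikelet-restricted *SEP1-4*-like gene), blank detections at
  0.28% of counts, sub-threshold segmentation artifacts, low-count cells,
  and a misexpression genotype with ectopic *VRT2* and a flattened gradient.

## Worked example

```bash
python examples/03_transect_gradients.py
```

```
P1WT: VRT2 basal/central ratio 3.47 (designed wildtype fold 3.46); co-expression across the spike: only-VRT2 15.6%, only-SEP 20.8%, both 1.1%
P1POL: VRT2 basal/central ratio 1.03 (designed wildtype fold 3.46); co-expression across the spike: only-VRT2 41.8%, only-SEP 8.1%, both 13.0%

misexpression flattens the basal enrichment: 1.03 vs wildtype 3.47 (a ratio near 1 means no axial restriction)
```

The wildtype spike recovers the designed 3.46-fold basal enrichment of the
rachis gradient gene; in the misexpression genotype the ratio collapses to
~1 and the two reciprocal genes, spatially exclusive in wildtype (1.1% of
cells co-expressing), are co-detected in 13% of cells.

The other examples cover QC (`01`), domain clustering and enrichment (`02`,
ARI 1.0 against generator truth on the 8-sample design), AM/LR group PCA
(`04`, Spearman ρ(PC1, position) = 0.98), pseudobulk dissection (`05`,
ρ ≈ 0.67 against a bulk reference) and the configured end-to-end pipeline
(`06`). A thin CLI wraps the same functions:

```bash
spikemap simulate --out bundle/ --seed 1
spikemap qc --matrix bundle/W4_P1WT/counts.csv --cells bundle/W4_P1WT/cells.csv --report qc.json
spikemap run --config config.yml
```

## Layout

```
src/spikemap/      io, geometry, synthetic, qc, domains, axis, pipeline, cli
examples/          one short narrative script per capability
tests/             pytest suite incl. end-to-end recovery tests
docs/methods.md    models, parameters, design choices, limitations
```
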