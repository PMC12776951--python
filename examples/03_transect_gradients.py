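"""Transect analysis of the reciprocal VRT2 / SEP1-4 gradients.

Slices wildtype and misexpression W4 spikes into 30 transverse bins along
the apical-basal axis and contrasts the pooled basal (bins 1-10) versus
central/apical (bins 11-30) expression of the rachis-restricted gradient
gene VRT2, plus the binarized co-expression of the two reciprocal genes.
The misexpression genotype carries ectopic VRT2 in spikelet tissues and a
flattened basal gradient.
"""

import pandas as pd

from spikemap import axis, domains, qc, synthetic

results = {}
for genotype in ("P1WT", "P1POL"):
    spec = synthetic.default_spec("W4", genotype, seed=3)
    spec.cells_per_domain = {k: 8 * v for k, v in spec.cells_per_domain.items()}
    polygons, cells, truth = synthetic.build_spike_layout(spec)
    counts, _ = synthetic.sample_counts(polygons, cells, truth, spec,
                                        emit_transcripts=False)
    filtered, cells_f, _ = qc.filter_cells(counts, cells)
    m = domains.normalize_counts(qc.strip_blanks(filtered))
    ratio = axis.basal_central_ratio(m, cells_f, "VRT2")
    results[genotype] = ratio

    labels = domains.DomainLabeling(
        labels=pd.Series(
            truth.cells.loc[m.obs_names, "true_domain"].astype("category").cat.codes,
            index=m.obs_names,
        )
    )
    cx = axis.coexpression_summary(m, labels, "VRT2", "SEP1-4").table
    row = cx.loc["all"]
    print(f"{genotype}: VRT2 basal/central ratio {ratio:.2f} "
          f"(designed wildtype fold 3.46); co-expression across the spike: "
          f"only-VRT2 {row['pct_only_a']:.1f}%, only-SEP {row['pct_only_b']:.1f}%, "
          f"both {row['pct_both']:.1f}%")

print(f"\nmisexpression flattens the basal enrichment: "
      f"{results['P1POL']:.2f} vs wildtype {results['P1WT']:.2f} "
      f"(a ratio near 1 means no axial restriction)")
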