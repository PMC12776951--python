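"""In-silico dissection versus a bulk RNA-seq reference.

Sums normalized counts over the cells of an ROI (here the whole spike) and
correlates the per-gene totals with a stage/section-matched bulk TPM table
by Spearman rank — the validation that imaging-based counts rank genes the
same way a physical microdissection does.
"""

from spikemap import axis, domains, qc, synthetic

spec = synthetic.default_spec("W4", "P1WT", seed=5)
polygons, cells, truth = synthetic.build_spike_layout(spec)
counts, _ = synthetic.sample_counts(polygons, cells, truth, spec,
                                    emit_transcripts=False)
filtered, cells_f, _ = qc.filter_cells(counts, cells)
m = domains.normalize_counts(qc.strip_blanks(filtered))

vector = axis.pseudobulk(m, list(m.obs_names))
reference = synthetic.synthetic_bulk_reference(spec)
rho = axis.pseudobulk_correlation(vector, reference)
print(f"pseudobulk of {m.n_obs} cells over {len(vector)} genes")
print(f"Spearman rho vs bulk TPM reference: {rho:.2f} "
      f"(rank concordance between imaging counts and bulk RNA-seq)")
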