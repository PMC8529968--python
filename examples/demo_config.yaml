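# Demo pipeline configuration: simulate a labeled single-cell pool, build the
# cell-type reference, benchmark deconvolution on pseudo-bulk mixtures, and
# run the gene-set screen + prognostic model on a synthetic survival cohort.
# Runs end-to-end in well under a minute on one CPU.
outdir: demo_out
seed: 7
n_types: 8
n_genes: 1200
cells_per_type: 120
markers_per_type: 20
marker_logfc: 2.0
n_mixtures: 60
cells_per_sample: 2000
n_cohort: 160
n_gene_sets: 120
beta_true: 1.2
effect_size: 2.0
couple_strength: 0.95
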