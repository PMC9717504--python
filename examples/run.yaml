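# Full-pipeline configuration for `retroloc run --config examples/run.yaml`.
# Thresholds are the analysis defaults; the simulation block replaces
# sam_paths/genes_gtf/repeats_gtf/design when working from synthetic data.
out_dir: retroloc_run
seed: 7
simulation:
  seed: 7
  depth: 50000
  replicates: 2
  n_genes: 60
  n_repeat_elements: 54
  copies_per_element: 6
  copy_identity: 0.5
  placement_mix: [0.5, 0.25, 0.25]
  nuclear_enrichment: 4.0
  spike_in_fraction: 0.01
max_mismatches: 10
top_n: 500
max_fold: 2.5
min_count_ratio: 10.0
min_count_dge: 20.0
fdr: 0.05
normalization: median_of_ratios
gene_mode: exonic
strand_mode: unstranded
run_metagene: true
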