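# Example run configuration for `quartetgc all --config examples/run.yaml`.
# Paths are resolved relative to this file; everything is written to outdir.
paths:
  outdir: pipeline_run
  # For real data, replace the simulate block with explicit inputs:
  # genomes:
  #   - {name: G1, cds_fasta: G1.cds.fa, gene_map: G1.genes.gff3}
  #   - {name: G2, cds_fasta: G2.cds.fa, gene_map: G2.genes.gff3}
  # hits: hits.tsv            # 12-column protein search table
  # annotation: annotation.tsv
  # centromeres: centromeres.tsv
simulate:
  n_genes_per_chromosome: 60
  conversion_fraction: 0.2
  omega: 0.3            # purifying selection; see docs/methods.md
  hit_fpr: 0.02
  inversion_rate: 0.5
  gene_loss_rate: 0.03
block_params:
  max_gap: 50
  min_anchors: 4
detector:
  bootstrap_reps: 1000
  wcv1_support_min: 0.95
stats:
  bin_width_bp: 100000
  perm_rounds: 10000
rng_seed: 0
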