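# Demo pipeline configuration: a toy genome with hypermethylation planted at
# bivalent promoters in one knockdown condition and body hypomethylation in a
# second, against a non-targeting control.
seed: 0

sim:
  n_chromosomes: 3
  chrom_length: 2000000
  n_genes: 300
  cgi_fraction_of_promoters: 0.6
  lcp_fraction_of_noncgi: 0.5
  depth: 500000
  beta_replicates: 4
  beta_noise_sd: 0.05
  kd_effects:
    - condition: siKD_k4
      stratum: bivalent
      fold: 2.5
    - condition: siKD_prc1
      stratum: body
      fold: 0.4

caller:
  window_size: 200
  gap_size: 600
  fragment_size: 300
  effective_genome_fraction: 0.854
  e_value: 1000
  fdr: 0.01

fold_threshold: 2.0
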