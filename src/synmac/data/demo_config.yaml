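# Bundled demo pipeline configuration: a small age x sex simulation with
# the study's subpopulation proportions, two old-vs-young contrasts and the
# branching trajectory. Runs in under a minute on one CPU.
seed: 11
n_permutations: 1000
divergence_draws: 5
simulate:
  n_genes: 400
  n_cells_per_group: 300
  marker_genes_per_subpop: 8
  marker_log2fc: 2.0
  de_effects:
    - {gene: 120, group: old_F, log2fc: 1.5, subpop: CD163+}
    - {gene: 121, group: old_F, log2fc: -1.5, subpop: CD163+}
    - {gene: 122, group: old_M, log2fc: 1.5, subpop: CX3CR1+}
qc:
  min_genes: 200
  min_umi: 5000
  max_mito: 0.05
embedding:
  n_hvg: 300
  n_pcs: 20
contrasts:
  - [old_M, young_M]
  - [old_F, young_F]
de:
  min_pct: 0.05
trajectory:
  root: Ly6C+
  terminals: [MHCII+, CX3CR1+, CD163+, Ctsk+]
  k: 15
  grid_size: 100
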