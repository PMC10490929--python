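# Small, fast demonstration run (synthetic database, ~1 minute).
# For a study-scale run, drop the `synthetic` overrides: the defaults are
# 111 compounds / 33 risk-flagged / 2000 genes / 100 pathways.
seed: 11
output_dir: demo_out
cell_types: [EC, SMC]

synthetic:
  n_compounds: 16
  n_risk: 6
  n_genes: 300
  n_pathways: 8
  pathway_size_range: [8, 14]
  n_risk_pathways: 3
  n_side_effects: 2
  seed: 11

queries:
  profiles: [risk_like, neutral]
  n_randomizations: 20

classify:
  side_effects: [arteriosclerosis]
  models: [ridge, random_forest, knn]
  k_folds: 3
  n_boot: 25
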