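# demo pipeline run on a small synthetic cohort
seed: 3
outdir: scratch/demo_run
stages: [simulate, score, resistance, communicate, axes, mutualism, growth]
simulate:
  n_patients: 4
  n_cells_per_sample: 120
  n_genes: 80
  n_pathways: 5
score:
  n_sets: 5
  genes_per_set: 10
mutualism:
  beta_grid_points: 9
  x_grid_points: 5
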