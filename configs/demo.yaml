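# Demo-scale configuration: ~5000 real cells, ~3000 planted clonotypes,
# a 14-cell dominant clonotype, 99.9% CD8+ cells, default noise levels.
seed: 0
sim:
  n_real_cells: 5000
  n_noise_barcodes: 5000
  n_samples: 3
  reads_per_real_cell: 300.0
  reads_per_noise_barcode: 10.0
  umi_length: 8
  umi_error_rate: 0.02
  n_clonotypes: 3000
  dominant_clone_size: 14
  clone_size_power: 2.2
  frac_cd8: 0.999
  multiplet_rate: 0.05
  tag_noise_rate: 0.02
stages:
  dbec_margin: 1.0
  knee_window: 5
  knee_tol: 0.01
  min_cells: 2
  min_effector_frac: 0.5
  score_noise_sd: 0.05
  n_pcs_umap: 4
  run_pca: true
  run_umap: false
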