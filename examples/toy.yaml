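# Three-site toy cohort: 60 subjects, 10 ROIs, three injected effect edges.
seed: 5
cohort:
  n_rois: 10
  n_timepoints: 80
  sites:
    - [s1, 10, 10]
    - [s2, 10, 10]
    - [s3, 10, 10]
  effect_edges: [[0, 1], [2, 3], [4, 5]]
  effect_size: 0.5
  site_shift_sd: 0.15
  base_density: 0.1
evaluation:
  layer_sets:
    - [LOFC]
    - [tHOFC]
    - [aHOFC]
    - [LOFC, tHOFC, aHOFC]
  classifiers: [svm]
  p_thresholds: [0.05]
dann:
  epochs: 100
  batch_size: 32
  lambda_grl: 1.0
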