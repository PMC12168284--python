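# Demo configuration: a small synthetic cohort exercising every stage.
# Runs end-to-end in a few minutes on one CPU; rerunning with the same
# config and seed reproduces all outputs bit-identically.
seed: 42

simulate:
  n_subjects_per_group: 15
  n_taxa: 60
  n_visits: 3

filters:
  prevalence_frac: 0.001
  abundance_rescue: 1000
  min_reads: 5000
  collapse: true

clr:
  pseudocount: 0.5

diversity:
  n_perm: 499

network:
  stars_reps: 10
  stability_threshold: 0.05
  set_size_group: 1.0
  set_size_global: 0.6
  min_cluster_size: 10

spatial:
  n_rounds: 50
  n_perm: 99
  restrict_tooth_health: H

signature:
  cv_folds: 5

mutans:
  low: 0.05
  high: 0.10
  n_trees: 300
  n_mc_samples: 0
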