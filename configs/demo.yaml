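# Small end-to-end demo: simulate everything, then run all analysis stages.
seed: 1
out_dir: runs/demo

simulate:
  n_transcripts: 400
  n_age_related: 80
  group2_fraction: 0.75
  n_housekeeping: 10
  slope_magnitude: 0.02
  cohorts:
    n_cohorts: 4
    samples_per_cohort: 60
    age_range: [20.0, 86.0]
    noise_sd: 0.25
    batch_shift_sd: 0.05
  probes:
    probes_per_transcript: 6
    multi_match_fraction: 0.05
    gc_bias_amplitude: 1.0
  twins:
    n_pairs: 40
    h2_coding: 0.8
    h2_noncoding: 0.5
  compounds:
    n_mimics: 5
    n_opposers: 5
    n_neutral: 90

age_scan:
  window1: [20.0, 55.0]
  window2: [51.0, 86.0]
  covariates: [vo2max, insulin_sensitivity]
  max_mean_q: 0.03

classify:
  zero_band: 0.1
  keep_min: 0.2
  cv_max: 0.05

screen:
  hit_threshold: 90.0

network:
  fdr_max: 0.01
  n_permutations: 1000
  max_transcripts: 150

heritability:
  n_bootstrap: 10000
  min_genes: 10
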