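# Full-pipeline run on a simulated wild-type-like F2 population.
seed: 7
n_individuals: 200
chromosomes: arabidopsis
sim:
  class1_mean: 1.8
  nu: 5.0
  class2_mean: 0.2
  geno_error_p: 0.02
  marker_spacing: 50000
  base_depth: 20.0
  noise_sd: 2.0
filter:
  min_qual: 100
  min_cov: 2.5
  min_lib_reads: 50000
call:
  window_markers: 15
  purity: 0.8
  min_segment_markers: 5
ploidy:
  trisomy: 1.2
  monosomy: 0.8
interference:
  n_sample: 400
  boot_iters: 1000
  bin_width: 3.5e6
landscape:
  window: 300000
rf:
  rf_cm: 21.8
  n_total: 4000
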