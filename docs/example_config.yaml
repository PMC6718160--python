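# Pipeline configuration. Every key is optional; defaults reproduce the
# reference study conditions. CLI flags (--seed) override file values.

simulate_data: true      # false: read fish_table / otolith_table instead
# fish_table: data/fish.csv
# otolith_table: data/otoliths.csv
n_ageing: 401            # size of the length-stratified ageing subsample
length_weight_model: linear   # or "power" (log-log allometric)

analysis:
  length_bin_width: 5.0       # cm size classes
  mcmc_iterations: 100000     # total maturity-ogive posterior draws
  thin: 100
  burn_in_fraction: 0.10
  credible_level: 0.90
  z_method: chapman_robson    # or catch_curve
  reading_used: "2"           # otolith reading for downstream ages
  mir_max_length: 50.0        # cm cutoff for marginal-increment analysis
  abi_exponent_mode: estimate # or fixed (then set abi_exponent)
  biological_intercept_length: 13.5   # cm, smallest sampled fish

simulate:
  n_fish: 455
  true_linf: 85.28            # cm
  true_k: 0.14                # 1/yr
  true_t0: 0.16               # yr
  length_cv: 0.08
  total_mortality_z: 0.9      # 1/yr
  max_age: 22
  l50_true: 38.5              # cm
  gsi_peak_months: [2, 3, 8, 9]
  reader_error_sd: 1.0        # ring-count SD at the reference age (8 yr)
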