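{
 "counters": {
  "detected": 93589,
  "detected_late": 1270,
  "discarded": 5141,
  "launched": 100000,
  "transmitted": 0
 },
 "mc_config": {
  "n_photons": 100000,
  "n_time_bins": 100,
  "n_z_bins": 25,
  "path_max_mm": 1000.0,
  "seed": 20160527,
  "t_max_ps": 3000.0,
  "z_hist_max_mm": 50.0
 },
 "medium": {
  "g": 0.0,
  "mu_a": 0.0,
  "mu_s_prime": 1.0,
  "n_in": 1.4,
  "n_out": 1.4
 },
 "seed": 20160527
}
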