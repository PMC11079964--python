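# Example wmcpp pipeline configuration (all keys optional; defaults shown).
# One file governs every stage; CLI flags override. See src/wmcpp/config.py.

seed: 1

simulate:                       # synthetic cohort (wmcpp.synth.SimConfig)
  n_participants: 25
  n_trials: 620
  sfreq_hz: 1000.0
  dt_shift_ms: 250.0            # shifted-lognormal decision-time law
  dt_lognorm_mu: 6.102
  dt_lognorm_sigma: 0.5
  onset_ms: 100.0               # accumulation onset after cue
  bound_uV: {selection: 10.0, preselected: 8.0}
  decay_tau_ms: 300.0
  pink_rms_uV: 12.0
  white_rms_uV: 6.0
  alpha_rms_uV: 4.0
  cue_evoked_amp_uV: 5.0
  p_condition: 1.0              # probability of the selection-required condition

preprocess:                     # wmcpp.preprocess.PreprocessConfig
  ref_channels: [M1, M2]
  target_sfreq_hz: 250.0
  cue_window_ms: [-250.0, 1500.0]
  resp_window_ms: [-1500.0, 500.0]
  cue_baseline_ms: [-250.0, 0.0]
  resp_baseline_ms: [0.0, 250.0]
  smooth_sigma_ms: 30.0
  dt_bounds_ms: [200.0, 2000.0]
  variance_z_threshold: 3.5

analysis:                       # wmcpp.cpp.AnalysisConfig
  cluster_channels: [Pz, CPz, POz, P1, P2]
  n_bins_fine: 100
  n_bins_coarse: 4
  slope_window_ms: [-500.0, -50.0]
  min_window_ms: 100.0

inference:
  n_permutations: 10000
  cluster_alpha: 0.05
  exhaustive: null              # auto (exhaustive when 2^n <= 2^14)
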