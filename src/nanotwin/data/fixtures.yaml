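# Central fixture-regime defaults. Values here define the synthetic world
# used by tests and the CLI; every entry can be overridden per call.
dish:
  cell_radius_um: [8.0, 14.0]        # semi-axis range of rendered cells
  nucleus_scale: [0.35, 0.5]         # nucleus semi-axes relative to cell
  tau_s_median: 12.0                 # depletion time constant, log-normal
  tau_s_sigma: 0.3                   # log-space sigma
  ros_c0_mM: [0.5, 2.0]              # initial ROS/RNS concentration range
  adherent_prob: 0.85
  escape_prob_adherent: 0.02
  escape_prob_loose: 0.7
  death_prob_per_attempt: 0.04
  membrane_compliance_um: [1.0, 3.0]
  max_place_tries: 2000
sensor:
  slope_pA_per_mM: 20.0
  intercept_pA: 0.0
  bias_voltage_V: 0.85
  noise_sd_pA: 0.5
  sample_rate_Hz: 1000.0
  detect_threshold_pA: 8.0
optics:
  pixel_size_um: 1.0
  frame_rate_Hz: 20.0
  background_level: 0.25
  cell_contrast: 0.25
  nucleus_contrast: -0.12
  needle_contrast: 0.45
  needle_width_px: 3.0
  noise_sd: 0.004
pairs:
  current_mean_pA: 10.0
  current_sd_pA: 4.0
  fluor_mean: 100.0
  fluor_sd: 30.0
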