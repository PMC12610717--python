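# Full study design: two atmospheres, the ten heating rates, default noise.
seed: 42
log_level: INFO
design:
  q_list: [0.1, 0.2, 0.5, 1, 2, 3, 5, 7, 10, 20]
  T_span_C: [30, 550]
  sampling_interval_s: 1
  atmospheres: [n2, air]
noise:
  mass_sigma: 0.0005
  temp_jitter_C: 2.0
  step_magnitude_rel_sigma: 0.03
  total_loss_rel_sigma: 0.02
kissinger:
  n_steps: 3
  delta_T: 2.0
  prominence_frac: 0.05
  mode: auto
fit:
  delta_m_mode: fixed_from_data
  fit_points: 400
  n_polish: 3
  max_nfev: 2000
predict:
  hold_temperatures_C: [150, 170, 190, 210, 230]
  hold_minutes: 60
  ramp_start_C: 30
  ramp_rate_C_per_min: 5
  resolution_s: 1
  thresholds: [0.01]
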