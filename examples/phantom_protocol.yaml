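acquisition:
  tr_ms: 2.54
  te_ms: 1.27
  flip_deg: 35.0
  ramp_pulses: 10
  n_phase_encodes: 65
  center_line_index: 33
  slice_thickness_mm: 6.0
  ir_pulse:
    duration_ms: 4.74
    mu: 5.0
    beta_per_s: 2235.0
    b1max_uT: 54.0
  excitation_pulse:
    duration_us: 490.0
    lobes: 3
    apodization: hann
  dt_us: 10.0
  initial_tis_ms:
  - 114.0
  - 350.0
  n_slice_spins: 21
  slice_fov_factor: 2.0
scheme: 5(3p)3
timing:
  rr_intervals_ms:
  - 1000.0
  - 1000.0
  - 1000.0
  - 1000.0
  - 1000.0
  - 1000.0
  - 1000.0
  - 1000.0
  - 1000.0
  - 1000.0
  - 1000.0
  - 1000.0
  trigger_delay_ms: 0.0
noise_sigma: 0.0
seed: 1
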