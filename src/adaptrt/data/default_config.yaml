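# Default study configuration (all values may be overridden; --seed on the
# CLI overrides master_seed). Distribution settings are documented in
# adaptrt.synthetic_cohort.CohortParams and adaptrt.dose_model.DoseModelParams.
master_seed: 20210804
n_patients: 32
n_fractions: 5
spacing_mm: 2.0
shift_scale: 1.0
dvh_bin_width_gy: 0.05
cohort:
  prostate_volume_mean_cc: 65.3
  prostate_volume_sd_cc: 26.3
  shift_sigma_mm: [1.0, 1.5, 1.0]
  shift_cap_mm: 10.0
  rectum_push_mm: 5.0
  fill_sigma: 0.35
  fill_bounds: [0.6, 1.6]
  target_axis_scale_sigma: 0.11
  target_axis_scale_bounds: [0.82, 1.25]
dose:
  prescription_ctv_gy: 40.0
  prescription_ptv_gy: 36.25
  oar_sparing_depth: 0.35
  oar_interface_margin_mm: 3.0
  noise_amplitude: 0.01
  noise_correlation_mm: 8.0
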