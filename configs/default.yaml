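profile: tiny
seed: 0
n_subjects: 300
epochs: 12
fractions:
- 0.7
- 0.15
- 0.15
contamination: 0.02
k_range:
- 2
- 8
bootstrap_B: 50
label_model:
  signal: volume
  prevalence_diabetes: 0.3
  sex_female_prob: 0.5
  age_mean: 48.0
  age_sd: 12.0
  bmi_mean: 28.0
  bmi_sd: 4.5
  visc_lower_base: 0.3
  visc_lower_sd: 0.08
  visc_lower_delta: 0.4
  visc_upper_base: 0.3
  visc_upper_sd: 0.08
  pattern_high: 0.55
  pattern_low: 0.15
  subcut_base: 0.25
  subcut_bmi_slope: 0.012
  subcut_sd: 0.05
  thigh_mean: 0.35
  thigh_sd: 0.1
  arm_mean: 0.3
  arm_sd: 0.08
  neck_mean: 0.25
  neck_sd: 0.08
  breast_female: 0.55
  breast_male: 0.15
  breast_sd: 0.08
  is_base: 18.0
  is_visc_slope: 16.0
  is_thigh_slope: 4.0
  is_noise_sd: 1.5
  is_floor: 0.5
  fasting_base: 4.9
  fasting_is_slope: 0.08
  fasting_noise_sd: 0.3
  g2h_base: 5.8
  g2h_is_slope: 0.25
  g2h_noise_sd: 0.8
  hba1c_base_pct: 5.2
  hba1c_is_slope: 0.05
  hba1c_noise_sd: 0.2
  fasting_dm_offset: 0.3
  fasting_dm_spread: 1.2
  g2h_dm_offset: 0.4
  g2h_dm_spread: 2.5
  hba1c_dm_offset_pct: 0.2
  hba1c_dm_spread_pct: 0.6
  dm_base_hazard: 0.02
  dm_hba1c_loghr: 0.9
  ma_base_hazard: 0.03
  ma_hba1c_loghr: 0.5
  uacr_log_mean: 2.1
  uacr_log_sd: 0.7
  uacr_hba1c_slope: 0.25
  censor_min: 0.25
  censor_max: 9.75
  admin_censor: 10.0
  missing_rate: 0.0
  thresholds:
    fasting_diabetes: 7.0
    g2h_diabetes: 11.1
    hba1c_diabetes_mmolmol: 48.0
    ifg_low: 5.6
    ifg_high: 6.9
    igt_low: 7.8
    igt_high: 11.0
    uacr_microalbuminuria: 30.0
augment:
  max_pad: 2
  rot_vertical_deg: 10.0
  rot_other_deg: 5.0
  noise_sd: 0.05
  zoom_range: 0.0
  pad_enabled: true
  rotation_enabled: true
  noise_enabled: true
  zoom_enabled: false
  crop_torso:
  - 0.25
  - 0.75
  crop_abdomen:
  - 0.4
  - 0.65
mixture:
  n_components: 4
  dim: 128
  separation: 3.0
  within_sd: 1.0
  weights: null
out_dir: runs/latest
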