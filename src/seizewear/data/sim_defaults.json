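{
 "n_subjects": 66,
 "age_min_months": 1,
 "age_max_months": 161,
 "sex_ratio_female": 0.5,
 "duration_hours": 24.0,
 "start_unix_ms": 1514764800000,
 "hr_infant_bpm": 115.0,
 "hr_child_bpm": 80.0,
 "hr_infant_knot_months": 12.0,
 "hr_child_knot_months": 60.0,
 "circadian_hr_amplitude_bpm": 5.0,
 "circadian_peak_hour": 14.0,
 "hr_ar_sd_bpm": 2.0,
 "hr_ar_phi": 0.95,
 "hr_slow_sd_bpm": 8.0,
 "hr_lf_amp_bpm": 3.0,
 "hr_hf_amp_bpm": 2.0,
 "gsr_base_us": 8.0,
 "gsr_age_slope_us_per_month": -0.03,
 "gsr_floor_us": 1.0,
 "gsr_day_delta_us": 0.5,
 "gsr_sex_female_delta_us": 0.3,
 "gsr_noise_sd_us": 0.6,
 "acc_noise_sd_g": 0.02,
 "gyr_noise_sd_dps": 2.0,
 "activity_bouts_per_hour": 4.0,
 "activity_bout_mean_s": 120.0,
 "activity_amp_g": 0.25,
 "activity_amp_dps": 25.0,
 "seizures_per_day": 5.6,
 "duration_probs": [
  0.813,
  0.103,
  0.032,
  0.023,
  0.011,
  0.018
 ],
 "max_seizure_duration_s": 600.0,
 "min_event_gap_s": 180.0,
 "effects": {
  "hr_delta_bpm": 25.0,
  "gsr_delta_us": 1.0,
  "acc_burst_g": 0.5,
  "gyr_burst_dps": 30.0,
  "hrv_suppression_factor": 0.4,
  "lfhf_gain": 2.0
 },
 "missing_rate": 0.05,
 "missing_span_mean_s": 120.0,
 "nonwear_rate": 0.05,
 "nonwear_span_mean_s": 1800.0,
 "seed": 0
}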