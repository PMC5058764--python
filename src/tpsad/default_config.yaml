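# Fully populated default run configuration.
# Any key may be overridden by a user config file or CLI flags.

constants:
  epithelial_fraction: 0.1      # PSA-secreting fraction of benign volume
  benign_secretion: 0.30        # ng/ml serum per cc of benign epithelium
  psa_exclusion_max: 20.0       # ng/ml eligibility cut-off
  gland_percentile_cut: 95.0    # empirical gland-size percentile cut

volumetry:
  spacing_mm: 3.5               # whole-mount section interval
  shrinkage_factor: 1.25        # formalin shrinkage correction

cohort_sim:
  n_patients: 1108
  grade_probs: [0.138, 0.765, 0.097]
  pt3_prob_low: 0.08
  pt3_prob_high: 0.70
  target_pt3: 0.304
  epe_rate: 0.294
  svi_rate: 0.06
  margin_prob_pt2: 0.20
  margin_prob_pt3: 0.35
  prostate_vol_median: 32.2
  prostate_vol_iqr: [24.2, 43.5]
  tumour_vol_median: 2.6
  tumour_vol_iqr: [1.3, 4.8]
  tumour_vol_shift_low: 0.6
  tumour_vol_shift_high: 2.0
  secretion_low_confined: 4.01
  secretion_high_invasive: 1.71
  psa_noise_sigma: 0.3
  missing_psa_rate: 0.007328990228013029   # 9 / 1228
  age_median: 61.5
  age_sd: 6.5
  age_range: [40.2, 79.0]
  intermediate_34_prob: 0.688
  high_pattern_probs: [0.5, 0.25, 0.15, 0.10]
  index_fraction_beta: [8.0, 2.0]
  log_hr_epe: 0.5187937934151676           # ln 1.68
  log_hr_svi: 0.6418538861723947           # ln 1.90
  log_hr_margins: 0.7514160886839211       # ln 2.12
  log_hr_grade_intermediate: 0.6780335427258538  # ln 1.97
  log_hr_grade_high: 1.6639011311269347    # ln 5.28
  log_hr_ln_tpsad: 0.0
  baseline_hazard: 0.0008                  # events per month, reference patient
  target_event_fraction: 0.232
  max_horizon_months: 3600.0

expression_sim:
  n_studies: 5
  n_genes: 1000
  samples_per_class: 20
  cassette_size: 25
  cassette_lfc: -2.0
  ar_lfc: 1.0
  noise_sigma: 0.5
  baseline_mean: 7.0
  baseline_sd: 1.0

volume_field: total
n_perm: 2000
alpha: 0.05
ihc_low_od: 0.8
ihc_high_od: 0.4
ihc_images_per_group: 8
ihc_region_size: 64
seed: 0
out_dir: tpsad_report
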