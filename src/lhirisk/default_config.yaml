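# Default configuration: every published value stated explicitly.
cohort:
  n: 77
  p_cmca: 0.429            # 33/77 complete MCA infarctions
  p_male: 0.532            # 41/77 men
  p_hypodensity_gt_one_third: [0.488, 0.159]
  p_hmcas: [0.5455, 0.25]
  p_brain_edema: [0.5455, 0.2955]
  p_chf: [0.10, 0.10]
  p_hypertension: [0.688, 0.688]   # 68.8% overall, no group difference
  p_diabetes: [0.40, 0.40]
  p_prior_stroke_or_tia: [0.25, 0.25]
  p_atrial_fibrillation: [0.40, 0.40]
  p_smoking: [0.35, 0.35]
  p_hypercholesterolemia: [0.35, 0.35]
  p_coronary_artery_disease: [0.15, 0.15]
  p_thrombolysis: [0.15, 0.15]
  p_craniectomy: [0.09, 0.0]
  age_mean: 70.7
  age_sd: 12.6
  age_range: [40, 94]
  nihss_admission_mean: [20.3, 15.6]   # (CMCA, IMCA)
  nihss_admission_sd: 5.0              # not published; plausible spread
  nihss_day5_mean: [20.8, 14.6]
  nihss_day5_increment_sd: 3.0
  mortality_intercept: -3.542          # calibrated: overall mortality 11.7%
  mortality_slope: 1.5                 # log-odds per mortality-score-2 point
  stroke_death_fraction: 0.9
  imca_fraction_range: [0.5, 0.95]
  ct_sign_correlation: 0.0
  seed: 0
analysis:
  nihss_admission_cutoff: 17   # CMCA-score severity component
  nihss_peak_cutoff: 26        # mortality-score-2 severity component
  chads2_cutoff: 4
  sip_delta: 2                 # NIHSS rise defining stroke in progression
  lhi_fraction: 0.5
  cmca_score_cutoff: 2
  mortality1_cutoff: 1
  mortality2_cutoff: 2
  nihss_window: peak           # peak | day5
  welch: false                 # pooled-variance t test by default
  chi2_correction: false       # uncorrected Pearson chi-square
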