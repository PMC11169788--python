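# Calibration constants of the synthetic cohort generator.
# Marginal targets follow the published characteristics of an AL-amyloidosis
# CMR cohort (n = 92): ECV 46 +/- 10 %, rest MBF 0.87 +/- 0.21 ml/min/g,
# MWE 3.61 +/- 1.68 mmHg.L/min/g, HR 77 +/- 12, SBP 117 +/- 18, DBP 69 +/- 12,
# LVEF 56 +/- 9, LV mass index 80 +/- 27 g/m^2, BSA 1.87 +/- 0.22 m^2.
# Structural paths: ECV->MBF -0.0073 per 1% (tertile means 0.97/0.85/0.81),
# MBF->MWE 1.86, direct ECV->MWE -0.0732 per 1% (-0.366 per 5%), which give
# an indirect effect of -0.068 per 5% ECV (16% of the total).
n_subjects: 92
ecv_mean_pct: 46.0
ecv_sd_pct: 10.0
ecv_lo_pct: 20.0
ecv_hi_pct: 70.0
path_a_mbf_per_ecv: -0.0073
path_b_mwe_per_mbf: 1.86
path_c_direct_per_ecv: -0.0732
mbf_intercept: 1.2058
mbf_resid_sd: 0.197
mwe_intercept: 5.359
mwe_resid_sd: 1.39
min_mbf: 0.05
min_mwe: 0.05
seg_ecv_sd_pct: 3.0
seg_mbf_sd: 0.10
seg_ecv_effect: -0.003
seg_rpp_effect: 0.2
slice_increment_mid: 0.05
slice_increment_apical: 0.10
gradient_tertiles: [middle, upper]
lge_log_or_per_ecv: 0.4383
lge_center_ecv_pct: 41.5
remission_fraction: 0.23
hct_mean: 0.40
hct_sd: 0.04
hr_mean: 77.0
hr_sd: 12.0
sbp_mean: 117.0
sbp_sd: 18.0
dbp_mean: 69.0
dbp_sd: 12.0
lvef_mean: 56.0
lvef_sd: 9.0
lv_mass_index_mean: 80.0
lv_mass_index_sd: 27.0
bsa_mean: 1.87
bsa_sd: 0.22
la_volume_index_mean: 48.0
la_volume_index_sd: 16.0
native_t1_mean_ms: 1232.0
native_t1_sd_ms: 119.0
nt_probnp_log_mean: 7.33
nt_probnp_log_sd: 1.4
troponin_log_mean: -3.5
troponin_log_sd: 1.0
dflc_log_mean: 3.0
dflc_log_sd: 1.2
age_mean: 62.0
age_sd: 8.0
male_fraction: 0.57
gls_mean: -16.1
gls_noise_sd: 3.5
nyha_fractions: [0.22, 0.43, 0.29, 0.06]
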