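# Reference configuration of the synthetic three-arm trial generator.
# Group-level means/SDs are the study conditions the generator emulates:
# baseline characteristics, phase-wise session physiology, habitual activity
# and intake levels, and group-by-time effect trajectories (training gains,
# partial detraining regression).  All values are data, not code, so the
# generator is reusable for other trial shapes.
version: 1
group_sizes: {C: 21, TR: 14, TRD: 14}
trunc_sd: 3.0
bmi_window: [25.1, 34.9]
attendance_rate: 0.94
weeks: {baseline: 0, mid: 20, post: 40}

baseline:           # per-group [mean, sd]
  C:
    age_yr: [36.0, 4.2]
    body_mass_kg: [80.2, 8.9]
    bmi: [29.6, 3.0]
    body_fat_pct: [46.7, 6.5]
    steps_day: [6399.7, 1851.3]
    vo2max_mlkgmin: [26.1, 3.2]
    one_rm_kg: [133.8, 29.7]
    waist_cm: [95.9, 5.3]
    hip_cm: [110.3, 6.5]
    rmr_kcal_day: [1501.1, 162.8]
  TR:
    age_yr: [36.4, 5.0]
    body_mass_kg: [78.0, 9.9]
    bmi: [28.4, 2.8]
    body_fat_pct: [47.5, 3.2]
    steps_day: [6330.7, 1279.0]
    vo2max_mlkgmin: [26.1, 4.4]
    one_rm_kg: [124.6, 22.4]
    waist_cm: [96.7, 8.8]
    hip_cm: [110.9, 6.5]
    rmr_kcal_day: [1451.6, 145.4]
  TRD:
    age_yr: [36.9, 4.3]
    body_mass_kg: [78.2, 7.8]
    bmi: [29.1, 3.0]
    body_fat_pct: [46.2, 3.9]
    steps_day: [6870.0, 2030.6]
    vo2max_mlkgmin: [27.4, 3.2]
    one_rm_kg: [131.4, 18.6]
    waist_cm: [96.4, 8.9]
    hip_cm: [110.9, 7.2]
    rmr_kcal_day: [1504.1, 220.3]

# not tabulated by group; chosen to land session %HRR near the observed range
resting_hr: [65.0, 8.0]
max_hr_test: [165.0, 11.0]
rer_rest: [0.85, 0.03]

# Phase-wise session physiology [mean, sd]; EPOC is drawn as kilocalories and
# stored as a pre-integrated oxygen volume.
phases:
  1:
    mean_hr: [118.5, 9.2]
    max_hr: [150.7, 12.2]
    lactate_pre: [1.61, 0.41]
    lactate_mid: [8.02, 0.90]
    lactate_post: [8.99, 1.09]
    ve_lmin: [55.71, 6.9]
    mean_vo2_mlkgmin: [18.05, 1.9]
    rer: [1.04, 0.06]
    rpe: [13.71, 1.0]
    epoc_kcal: [11.0, 2.8]
  2:
    mean_hr: [130.8, 12.6]
    max_hr: [157.6, 11.8]
    lactate_pre: [1.54, 0.25]
    lactate_mid: [11.57, 0.72]
    lactate_post: [11.31, 0.77]
    ve_lmin: [62.00, 7.0]
    mean_vo2_mlkgmin: [19.26, 1.9]
    rer: [1.08, 0.05]
    rpe: [14.86, 0.9]
    epoc_kcal: [26.1, 4.6]
  3:
    mean_hr: [143.2, 12.1]
    max_hr: [164.9, 11.6]
    lactate_pre: [1.36, 0.33]
    lactate_mid: [12.31, 1.63]
    lactate_post: [11.78, 1.94]
    ve_lmin: [68.71, 5.9]
    mean_vo2_mlkgmin: [23.64, 2.0]
    rer: [1.10, 0.06]
    rpe: [16.00, 0.9]
    epoc_kcal: [34.7, 3.4]
  4:
    mean_hr: [151.1, 11.3]
    max_hr: [172.5, 9.9]
    lactate_pre: [1.53, 0.40]
    lactate_mid: [12.42, 1.40]
    lactate_post: [11.99, 1.40]
    ve_lmin: [73.50, 5.5]
    mean_vo2_mlkgmin: [23.84, 2.4]
    rer: [1.11, 0.07]
    rpe: [16.14, 0.5]
    epoc_kcal: [35.3, 3.8]

# assessment timepoint whose body mass a monitored session uses
phase_mass_timepoint: {1: baseline, 2: 20wk, 3: 20wk, 4: 40wk}
# which groups train in which phase
phase_groups: {1: [TR, TRD], 2: [TR, TRD], 3: [TR, TRD], 4: [TR]}

# Energy-chain constants used when analysing generated sessions.  The lactate
# oxygen equivalent and the session-duration aerobic integral are the values
# that close the generated phase-2 energy decomposition on the reference total
# (back-calculated from the tabulated component means; the library defaults
# remain 3.0 and the metabolic duration).
energy:
  lactate_o2_equiv: 7.2
  aee_duration_mode: session

# Habitual-activity targets per group: minutes per band over a 1440-min day
# (sleep scored sedentary) and steps per day.
activity:
  C:    {sedentary_min: 1205.5, light_min: 198.5, moderate_min: 34.9, vigorous_min: 1.05, steps_day: 6399.7}
  TR:   {sedentary_min: 1230.3, light_min: 179.1, moderate_min: 29.6, vigorous_min: 0.98, steps_day: 6330.7}
  TRD:  {sedentary_min: 1203.8, light_min: 191.8, moderate_min: 42.4, vigorous_min: 0.91, steps_day: 6870.0}

intake:
  target_kcal: {C: 1829.9, TR: 1840.5, TRD: 1839.6}
  # day-level energy noise, calibrated so a 7-day mean stays inside the
  # +-5% prescription tolerance in ~97% of weeks
  day_noise_cv: 0.06
  macro_bands: {cho: [55, 60], pro: [15, 20], fat: [20, 25]}

# Group-by-time effect profile: multiplicative change of each outcome at
# 20 and 40 weeks relative to baseline, per group, plus the within-subject
# measurement noise CV.  Derived outcomes are computed per subject from the
# primaries (bmi from mass/height, whr from waist/hip, fat partition from
# mass and fat percent).
effects:
  body_mass_kg:   {C: [1.0025, 1.0087], TR: [0.9513, 0.9410], TRD: [0.9655, 0.9808], noise_cv: 0.010}
  body_fat_pct:   {C: [1.0086, 1.0214], TR: [0.9137, 0.8842], TRD: [0.9481, 0.9697], noise_cv: 0.020}
  waist_cm:       {C: [1.0021, 1.0177], TR: [0.9390, 0.9317], TRD: [0.9264, 0.9751], noise_cv: 0.010}
  hip_cm:         {C: [1.0063, 1.0172], TR: [0.9739, 0.9729], TRD: [0.9811, 0.9919], noise_cv: 0.010}
  rmr_kcal_day:   {C: [1.0043, 1.0151], TR: [1.0584, 1.1008], TRD: [1.0890, 1.0138], noise_cv: 0.030}
  vo2max_mlkgmin: {C: [0.9885, 0.9808], TR: [1.2184, 1.2682], TRD: [1.1533, 1.0766], noise_cv: 0.040}
  one_rm_kg:      {C: [0.9963, 1.0127], TR: [1.1533, 1.2721], TRD: [1.1279, 1.1179], noise_cv: 0.040}
  bmi:            {derived: true}
  whr:            {derived: true}
  fat_mass_kg:    {derived: true}
  ffm_kg:         {derived: true}

# within-subject correlation for the abstract panel generator used in
# statistical calibration
icc: 0.7
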