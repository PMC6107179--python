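# Methods

## Scope and model

The package implements the measurement-to-inference chain of a
three-arm, 40-week training/detraining trial in previously sedentary
overweight/obese women: a control arm (n = 21), a training arm (n = 14,
40 weeks of tri-weekly circuit training in four progressive phases) and a
training–detraining arm (n = 14, training through week 20, then
cessation).  Outcomes are assessed at baseline, 20 and 40 weeks.

Five computational layers stack on each other:

1. **Resting metabolism.** RMR (kcal·day⁻¹) from steady-state resting gas
   exchange by the abbreviated Weir equation with the classical
   coefficients 3.941 kcal·L⁻¹ O₂ and 1.106 kcal·L⁻¹ CO₂, scaled by 1440
   min·day⁻¹.  The respiratory exchange ratio is validated to (0.6, 1.3)
   with a warning, not an error, outside.

2. **Session energy decomposition.** TEE = AEE + ANEE + EPOC.
   * AEE = V̇O₂ (mL·kg⁻¹·min⁻¹) × mass × duration / 1000 × 5.05 kcal·L⁻¹
     (21.14 kJ·L⁻¹).  Which duration the integral uses is configurable
     (`aee_duration_mode`): the *metabolic* duration (default), the
     work-interval *circuit* arithmetic, or the full *session* duration.
   * ANEE converts net lactate accumulation (post − pre, clipped at zero
     because recovery sessions can end below baseline) to an oxygen
     equivalent.  The library default is the di Prampero convention of
     3.0 mL O₂·kg⁻¹·mM⁻¹; the constant is deliberately a config value —
     see *Calibration* below.
   * EPOC accepts a minute-sampled V̇O₂-above-rest trace or a
     pre-integrated litre volume.  Trace samples are minute averages, so
     the integral is their sum (the trapezoid rule over cumulative-volume
     bin edges reduces to exactly that).
   * Training load: METs = V̇O₂/3.5 (the standard MET bridge),
     MET·hours = METs × metabolic duration/60, weekly load ×3 sessions.

   Per-phase durations: session durations are 23/38/41/41 min
   (phases 1–4); the *metabolic* durations over which METs and kcal/min
   are expressed are 18/30/36/36 min — the unique values consistent with
   the reference MET·hour and kcal/min chains; the circuit arithmetic
   (exercises × rounds × interval = 20/33/36/36 min) is retained as a
   selectable alternative.

3. **Habitual activity.** 60-s epochs; non-wear is a Choi-style rule on
   vector magnitude (≥90-min zero runs, absorbing nonzero interruptions
   of ≤2 min flanked by ≥30 min of zeros on each side).  Intensity bands
   use vector-magnitude cut-points with sedentary defined as ≤199 cpm
   (the printed bands leave 199–200 unassigned; contiguous integer bands
   are used) and vigorous open above 6167 cpm (the 9642 upper edge is a
   reporting band edge, not a cap).  Per-epoch activity kcal and METs use
   Freedson-style vertical-axis equations gated at >1951 cpm; both gates
   and coefficients are config constants, chosen because they land
   synthetic days inside the reference daily-kcal range.  Validity: days
   with ≥600 wear minutes count; subjects need ≥4 such days; partial
   first/last days never count.

4. **Intake and ledger.** Recall days are summarized with Atwater 4/4/9
   factors; macro shares are computed on energy from grams summed over
   the period (not a mean of daily percentages).  The isocaloric target
   is RMR × activity factor (default 1.3, flagged as an assumption).
   The ledger is an accounting identity — intake − (RMR + habitual
   activity + exercise cost) — with no adaptive-thermogenesis model, no
   double-counting correction between RMR and accelerometer kcal, and
   the thermic effect of food off by default (an optional fixed-fraction
   hook exists).  Fat equivalence uses 7700 kcal·kg⁻¹ (configurable; the
   reference trial's own arithmetic implies ≈7490).

5. **Statistics.** The "two-way repeated-measures ANOVA" is implemented
   as a mixed (split-plot) design — group between, time within —
   matching the data structure; Mauchly's test runs on the within
   factor and Greenhouse–Geisser df correction applies conditionally
   when Mauchly p < 0.05 (an always-correct mode is available).  The
   ANOVA itself is delegated to pingouin; an explicit sums-of-squares
   oracle in the test suite checks the F statistics to 1e-8.
   Hedge's g uses the pooled-SD d with J = 1 − 3/(4N − 9) and the
   large-sample CI variance (N/(n₁n₂) + g²/(2(N − 2))).  Published
   phase-contrast effect sizes are *not* reproducible from the published
   means/SDs under any standard pooled formula (≈5 % discrepancies); the
   divergence is reported by the tests, not silently matched.  Post-hoc
   family: all pairwise groups within timepoint (independent t) plus all
   pairwise timepoints within group (paired t), Bonferroni-adjusted with
   m = family size.  ANCOVA adjusts group × time means for centred
   subject-level covariates via OLS; zero-slope covariates leave raw
   means untouched by construction.  Incomplete subjects are dropped
   (complete-case) with a logged count.

## Calibration of the session energy chain

The reference tables' anaerobic energy values imply an effective lactate
O₂ equivalent of ≈7.2 mL·kg⁻¹·mM⁻¹ (back-calculated consistently across
all four phases), not the textbook 3.0, and the tabulated aerobic
components are consistent with the *session* duration at phase 2 but not
with any single duration across all phases.  The synthetic trial's
reference configuration therefore sets `lactate_o2_equiv: 7.2` and
`aee_duration_mode: session`, which closes the generated phase-2 energy
decomposition on the reference total (326.8 kcal) to within a few
percent; phases 1, 3 and 4 deviate by up to ≈18 % under the same
constants, which is a property of the source arithmetic, not of the
implementation.  The library defaults remain the textbook values.

## The synthetic trial generator

The generator's defaults are the study conditions: group sizes 21/14/14,
baseline distributions, phase-wise session physiology, activity and
intake targets, and group × time effect multipliers computed from the
reference group means (training gains at both timepoints; detraining
regression that stays above baseline; slight control-arm drift with fat
up and endurance down).  Everything is data in a versioned YAML, not
code.

Specific design choices, where the design was genuinely open:

* **Baselines** are truncated normals (±3 SD, plus physiological floors)
  to exclude impossible physiology.  BMI is drawn inside the trial's
  inclusion window (25.1–34.9 kg·m⁻²) and height derived as
  √(mass/BMI): body-mass moments stay on target and every recomputed
  BMI respects the window, at the cost of a wider height SD (≈0.13 m)
  than the reference (0.05 m).
* **Resting heart rate (65 ± 8), treadmill-test maximal heart rate
  (165 ± 11) and resting RER (0.85 ± 0.03)** are not tabulated by group;
  values were chosen once so that session %HRR lands in the observed
  range and resting gas exchange reproduces the drawn RMR through the
  Weir equation exactly.
* **Sessions** draw each phase's physiology from the tabulated
  means/SDs, enforcing lactate ordering (mid, post ≥ pre) and
  mean ≤ max HR per draw; EPOC is drawn in kcal and stored as a
  pre-integrated volume.  A session uses the body mass of the assessment
  its phase maps to (phase 1 → baseline, 2–3 → 20 wk, 4 → 40 wk).
* **Accelerometer streams**: wear minutes follow a two-state
  (active/inactive) Markov chain (mean active run 8 min) whose
  stationary activity fraction equals the band targets; active minutes
  get a band by calibrated probabilities and a log-uniform vector
  magnitude within the band, so realized band minutes and steps are
  unbiased for the targets.  Step rates per band are rescaled to the
  steps/day target.  Sedentary minutes (sleep included — the reference
  daily band minutes sum to 1440, i.e. sleep is scored sedentary) carry
  occasional low nonzero counts so that only deliberately inserted
  non-wear blocks form long zero runs.
* **Diet recalls**: lognormal day-level energy noise, bias-corrected so
  the weekly mean is the target.  The day CV default is 0.06, calibrated
  so a 7-day mean stays inside the ±5 % prescription tolerance in ≈97 %
  of weeks — a generator contract, tighter than free-living day-to-day
  variability (~15 %).
* **Outcome trajectories** are multiplicative: subject baseline ×
  group × time multiplier × lognormal measurement noise.  Derived
  outcomes (BMI, WHR, fat/fat-free partition) are recomputed per subject
  from the primaries so their identities hold exactly in the generated
  data.  Per-outcome noise CVs (1–4 %) reflect measurement
  repeatability; the abstract panel generator used for statistical
  calibration instead uses a subject random intercept with ICC 0.7 and a
  per-timepoint variance-scaling switch to inject sphericity violations.
* **Determinism**: all randomness flows from one integer seed through
  spawned child generators in fixed order; identical (config, seed)
  reproduce every output file byte-identically.

What the generator does **not** emulate: within-session heart-rate time
series, dropout/attrition processes, seasonal or day-of-week activity
structure, correlated baseline covariates beyond the enforced identities,
or recall under-reporting.  Passing round-trip tests therefore
demonstrates that the analysis stages recover what the generator encodes
— unbiased band minutes, intake targets, effect directions — not that
they would be robust to every artefact of field data.

## Numerical choices and degenerate inputs

* Negative lactate accumulation clips to zero; zero gas exchange gives
  zero RMR; an empty EPOC trace gives 0 kcal.
* A zero-variance outcome panel returns F = 0, p = 1 directly rather
  than 0/0.
* Greenhouse–Geisser epsilon is bounded in (1/(k−1), 1]; corrected
  p-values are recomputed from the F distribution at ε-scaled dfs (for
  the interaction as well as the within effect).
* Collinear ANCOVA covariates (|r| > 0.999) are flagged, not dropped.
* Wear-invalid subject-timepoints are excluded from activity and ledger
  summaries with their IDs logged in the report.
* Problem sizes in the default test run are scaled for a single CPU:
  500 null replicates for type-I calibration, 200 replicate weeks for
  intake calibration, 500 Monte-Carlo sessions for the energy chain,
  20 replicate trials for effect-direction recovery.

## Known limitations

* The ledger is bookkeeping, not physiology: no body-mass trajectory
  model, no adaptive thermogenesis, and RMR/activity double counting is
  inherited from the source definition.
* Between-group contrasts at n = 14/group carry baseline sampling noise
  of several percentage points; simulated cross-group percent
  differences scatter accordingly around their design values.
* The Freedson-era count equations are a convention, not a calorimetric
  truth; activity kcal should be read as a consistent index rather than
  an absolute measurement.
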