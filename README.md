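# ergotrial

Energy-balance analysis for exercise-training trials in previously
sedentary overweight/obese adults, built around a three-arm (control /
training / training–detraining) circuit-training design with assessments
at baseline, 20 and 40 weeks.

The package is aimed at exercise physiologists and biostatisticians who
need the full chain from raw measurements to trial-level inference:

* **Resting metabolism** — 24-h resting metabolic rate from steady-state
  resting gas exchange via the Weir equation,
  RMR = (3.941·V̇O₂ + 1.106·V̇CO₂) · 1440 kcal·day⁻¹.
* **Session energy cost** — total energy expenditure of a monitored
  session decomposed as TEE = AEE + ANEE + EPOC: an aerobic term
  (session V̇O₂ × mass × duration at 5.05 kcal·L⁻¹ O₂), a lactate-based
  anaerobic term (Δ[La⁻] × O₂-equivalent × mass), and the excess
  post-exercise oxygen consumption integral.  Training load is expressed
  as METs (V̇O₂/3.5), MET·hours, and MET·hours·week⁻¹.
* **Habitual activity** — 60-s accelerometer epochs with Choi-style
  non-wear detection (90-min zero-count window, 2-min spike tolerance,
  30-min flanks), vector-magnitude cut-points (sedentary ≤199, light
  200–2689, moderate 2690–6166, vigorous ≥6167 cpm), wear-validity rules
  (≥4 days, ≥10 h/day) and Freedson-style activity kcal/METs.
* **Diet intake** — 7-day recalls summarized with Atwater 4/4/9 factors
  and checked against an isocaloric prescription (55–60 % CHO, 15–20 %
  protein, 20–25 % fat).
* **Energy ledger** — the daily accounting identity
  balance = intake − (RMR + habitual activity + exercise cost), rolled up
  to weeks and periods and converted to a fat-mass equivalent at
  7700 kcal·kg⁻¹.
* **Trial statistics** — mixed (group × time) repeated-measures ANOVA
  with Mauchly's test and conditional Greenhouse–Geisser correction,
  Bonferroni post-hoc families, bias-corrected Hedge's g
  (J = 1 − 3/(4N − 9)) with 95 % CI and magnitude bands, and ANCOVA
  adjustment for intake and steps/day.
* **Synthetic trial generator** — a fully seeded in-silico trial
  (cohort, sessions, epoch streams, recalls, outcome trajectories) with a
  ground-truth manifest, so every stage is testable round-trip.

## Worked example

Energy decomposition of a mid-training monitored session (group-mean
physiology, 74.2 kg participant), using the trial's calibrated constants
(session-duration aerobic integral, 7.2 mL·kg⁻¹·mM⁻¹ lactate equivalent):

```python
from ergotrial.config import EnergyConstants
from ergotrial.physiology import SessionPhysiology, session_energy
from ergotrial.ledger import day_balance, week_balance

session = SessionPhysiology(
    phase=3, mean_hr=143.2, max_hr=164.9,
    lactate_pre=1.36, lactate_mid=12.31, lactate_post=11.78,
    mean_vo2=23.64, rpe=16.0, epoc_litres=34.7 / 5.05,
)
constants = EnergyConstants(lactate_o2_equiv=7.2, aee_duration_mode="session")
print(session_energy(session, 74.2, constants))
# {'aee_kcal': 363.18, 'anee_kcal': 28.11, 'epoc_kcal': 34.7,
#  'tee_kcal': 426.0, 'mets': 6.75, 'met_hours': 4.05,
#  'weekly_met_hours': 12.16, 'kcal_per_min': 11.83}

ex = day_balance(1840.5, 1536.4, 160.0, 426.0)   # exercise day
rest = day_balance(1840.5, 1536.4, 160.0)        # non-exercise day
print(round(ex.balance_kcal, 1), round(rest.balance_kcal, 1),
      round(week_balance(ex, rest, 3), 1))
# -281.9 144.1 -269.3
```

The session burns 426 kcal at 6.75 METs (4.05 MET·h, 12.2 MET·h·week⁻¹
over three sessions); on a training day the participant ends ~280 kcal in
deficit, on a rest day ~140 kcal in surplus, for a net weekly deficit of
~270 kcal once the elevated mid-training RMR is booked.

A complete synthetic trial and its analysis:

```bash
ergotrial simulate --out-dir trial --seed 1
ergotrial run --in-dir trial --out-dir trial/analysis
```

which writes per-subject ledgers, group summary tables, effect reports
(ANOVA + post-hoc + Hedge's g) and a markdown/JSON report bundle with an
embedded provenance manifest.

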