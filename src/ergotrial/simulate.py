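"""Synthetic three-arm trial generator.

Generates a complete in-silico randomized trial with known ground truth —
a cohort with internally consistent anthropometry, phase-wise monitored
exercise sessions, minute-epoch accelerometer streams, 7-day diet recalls
and longitudinal outcome trajectories — so every pipeline stage can be
tested round-trip without external data.

Design notes
------------
* Baselines are truncated normals (default +-3 SD) so no impossible
  physiology is drawn; counts and intake use lognormal noise.
* BMI is drawn inside the trial's inclusion window (25.1-34.9 kg/m2) and
  height derived as sqrt(mass/BMI), keeping body-mass moments on target
  while every recomputed BMI respects the window.
* Accelerometer wear minutes follow a two-state (active/inactive) Markov
  chain; active minutes receive an intensity band at calibrated
  probabilities and a log-uniform vector magnitude within the band, so
  realized band minutes and steps are unbiased for their targets.
* Sedentary minutes (sleep included) carry occasional low nonzero counts,
  so only deliberately inserted non-wear blocks form the long zero runs the
  non-wear detector looks for.
* All randomness flows from one integer seed through spawned child
  generators in a fixed order: identical (config, seed) reproduce the
  outputs bit-identically.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import EnergyConstants
from .physiology import SessionPhysiology

__all__ = [
    "TrialConfig",
    "load_trial_config",
    "gen_cohort",
    "gen_trajectories",
    "gen_session",
    "gen_sessions_frame",
    "gen_accel_week",
    "gen_diet_week",
    "gen_panel",
    "simulate_trial",
]

TIMEPOINTS = ("baseline", "20wk", "40wk")
PRIMARY_OUTCOMES = (
    "body_mass_kg", "body_fat_pct", "waist_cm", "hip_cm",
    "rmr_kcal_day", "vo2max_mlkgmin", "one_rm_kg",
)
DERIVED_OUTCOMES = ("bmi", "whr", "fat_mass_kg", "ffm_kg")
ALL_OUTCOMES = PRIMARY_OUTCOMES + DERIVED_OUTCOMES

_START_DATE = pd.Timestamp("2016-02-01")  # a Monday


class TrialConfig(BaseModel):
    """Generator settings: group sizes, distributions and effect profile."""

    model_config = ConfigDict(extra="allow")

    version: int = 1
    group_sizes: dict[str, int]
    trunc_sd: float = 3.0
    bmi_window: tuple[float, float] = (25.1, 34.9)
    attendance_rate: float = 0.94
    weeks: dict[str, float]
    baseline: dict[str, dict[str, tuple[float, float]]]
    resting_hr: tuple[float, float]
    max_hr_test: tuple[float, float]
    rer_rest: tuple[float, float]
    phases: dict[int, dict[str, tuple[float, float]]]
    phase_mass_timepoint: dict[int, str]
    phase_groups: dict[int, list[str]]
    energy: dict = Field(default_factory=dict)
    activity: dict[str, dict[str, float]]
    intake: dict
    effects: dict[str, dict]
    icc: float = 0.7

    @model_validator(mode="after")
    def _validate(self) -> "TrialConfig":
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 2")
        for outcome in ALL_OUTCOMES:
            if outcome not in self.effects:
                raise ValueError(f"effect profile missing outcome '{outcome}'")
        for name, profile in self.effects.items():
            if profile.get("derived"):
                continue
            for g in self.group_sizes:
                mults = profile.get(g)
                if mults is None or len(mults) != 2:
                    raise ValueError(
                        f"effect profile for '{name}' must give [mid, post] "
                        f"multipliers for group {g}"
                    )
        if self.bmi_window[0] >= self.bmi_window[1]:
            raise ValueError("invalid BMI window")
        return self

    def energy_constants(self) -> EnergyConstants:
        """Energy-chain constants used when analysing generated sessions."""
        return EnergyConstants(**self.energy)


def load_trial_config(path: str | Path | None = None) -> TrialConfig:
    """Load a trial configuration; defaults to the packaged reference trial."""
    if path is None:
        text = (
            resources.files("ergotrial.data").joinpath("trial_defaults.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    return TrialConfig.model_validate(yaml.safe_load(text))


def _truncnorm(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int | None = None,
    lo: float = -np.inf,
    hi: float = np.inf,
    n_sd: float = 3.0,
):
    """Truncated-normal draws by rejection (bounds: mean +- n_sd*sd and [lo, hi])."""
    lo = max(lo, mean - n_sd * sd)
    hi = min(hi, mean + n_sd * sd)
    if lo >= hi:
        raise ValueError(f"impossible truncation bounds [{lo}, {hi}]")
    if sd == 0:
        return np.full(size, mean) if size else mean
    n = size or 1
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out if size else float(out[0])


def gen_cohort(config: TrialConfig, seed: int | np.random.Generator) -> pd.DataFrame:
    """Draw the baseline cohort, one row per subject.

    Internally consistent: fat mass + fat-free mass = body mass, BMI is the
    recomputed mass/height^2 and lies in the inclusion window, resting gas
    exchange reproduces the drawn RMR through the Weir equation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = config.trunc_sd
    rows = []
    idx = 0
    for group in config.group_sizes:
        n = config.group_sizes[group]
        b = config.baseline[group]
        mass = _truncnorm(rng, *b["body_mass_kg"], size=n, lo=40, n_sd=k)
        bmi = _truncnorm(
            rng, *b["bmi"], size=n,
            lo=config.bmi_window[0], hi=config.bmi_window[1], n_sd=k,
        )
        height = np.sqrt(mass / bmi)
        fat_pct = _truncnorm(rng, *b["body_fat_pct"], size=n, lo=15, hi=60, n_sd=k)
        fat_mass = mass * fat_pct / 100.0
        age = _truncnorm(rng, *b["age_yr"], size=n, lo=30, hi=45, n_sd=k)
        steps = _truncnorm(rng, *b["steps_day"], size=n, lo=500, n_sd=k)
        vo2max = _truncnorm(rng, *b["vo2max_mlkgmin"], size=n, lo=10, n_sd=k)
        one_rm = _truncnorm(rng, *b["one_rm_kg"], size=n, lo=30, n_sd=k)
        waist = _truncnorm(rng, *b["waist_cm"], size=n, lo=50, n_sd=k)
        hip = _truncnorm(rng, *b["hip_cm"], size=n, lo=60, n_sd=k)
        rmr = _truncnorm(rng, *b["rmr_kcal_day"], size=n, lo=800, n_sd=k)
        rest_hr = _truncnorm(rng, *config.resting_hr, size=n, lo=40, n_sd=k)
        max_hr = _truncnorm(rng, *config.max_hr_test, size=n, lo=120, n_sd=k)
        max_hr = np.maximum(max_hr, rest_hr + 40)
        rer = _truncnorm(rng, *config.rer_rest, size=n, lo=0.7, hi=1.0, n_sd=k)
        for i in range(n):
            rows.append({
                "subject_id": f"S{idx:03d}",
                "group": group,
                "age_yr": age[i],
                "body_mass_kg": mass[i],
                "height_m": height[i],
                "bmi": bmi[i],
                "body_fat_pct": fat_pct[i],
                "fat_mass_kg": fat_mass[i],
                "ffm_kg": mass[i] - fat_mass[i],
                "steps_day": steps[i],
                "vo2max_mlkgmin": vo2max[i],
                "one_rm_kg": one_rm[i],
                "waist_cm": waist[i],
                "hip_cm": hip[i],
                "whr": waist[i] / hip[i],
                "rmr_kcal_day": rmr[i],
                "resting_hr": rest_hr[i],
                "max_hr_test": max_hr[i],
                "rer_rest": rer[i],
            })
            idx += 1
    return pd.DataFrame(rows)


def gen_trajectories(
    cohort: pd.DataFrame,
    config: TrialConfig,
    seed: int | np.random.Generator,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Longitudinal outcome panels plus a ground-truth manifest.

    Each primary outcome follows value = baseline x group multiplier x
    lognormal measurement noise at every timepoint; derived outcomes (BMI,
    WHR, fat partition) are recomputed per subject from the primaries so the
    identities hold in the generated data exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(cohort)
    values: dict[str, dict[str, np.ndarray]] = {}
    for outcome in PRIMARY_OUTCOMES:
        profile = config.effects[outcome]
        cv = float(profile.get("noise_cv", 0.02))
        base = cohort[outcome].to_numpy()
        mults = np.ones((n, 3))
        for g in config.group_sizes:
            mask = (cohort["group"] == g).to_numpy()
            mid, post = profile[g]
            mults[mask, 1] = mid
            mults[mask, 2] = post
        noise = np.exp(rng.normal(0.0, cv, size=(n, 3)) - cv**2 / 2.0)
        vals = base[:, None] * mults * noise
        values[outcome] = {tp: vals[:, j] for j, tp in enumerate(TIMEPOINTS)}

    height = cohort["height_m"].to_numpy()
    mass = values["body_mass_kg"]
    fat_pct = values["body_fat_pct"]
    values["bmi"] = {tp: mass[tp] / height**2 for tp in TIMEPOINTS}
    values["whr"] = {
        tp: values["waist_cm"][tp] / values["hip_cm"][tp] for tp in TIMEPOINTS
    }
    values["fat_mass_kg"] = {tp: mass[tp] * fat_pct[tp] / 100.0 for tp in TIMEPOINTS}
    values["ffm_kg"] = {
        tp: mass[tp] - values["fat_mass_kg"][tp] for tp in TIMEPOINTS
    }

    panels = {}
    for outcome in ALL_OUTCOMES:
        recs = []
        for tp in TIMEPOINTS:
            for i in range(n):
                recs.append({
                    "subject_id": cohort["subject_id"].iat[i],
                    "group": cohort["group"].iat[i],
                    "timepoint": tp,
                    "value": float(values[outcome][tp][i]),
                })
        panels[outcome] = pd.DataFrame(recs)

    truth = {}
    for outcome in ALL_OUTCOMES:
        per_group = {}
        for g in config.group_sizes:
            mask = (cohort["group"] == g).to_numpy()
            means = [float(values[outcome][tp][mask].mean()) for tp in TIMEPOINTS]
            profile = config.effects[outcome]
            if profile.get("derived"):
                base = cohort.loc[mask, outcome].to_numpy().mean()
                mults = [means[1] / means[0], means[2] / means[0]]
                configured = None
            else:
                mults = list(map(float, profile[g]))
                configured = mults
            per_group[g] = {
                "multipliers": mults,
                "configured": configured,
                "expected_direction_mid": int(np.sign(round(mults[0] - 1.0, 6))),
                "expected_direction_post": int(np.sign(round(mults[1] - 1.0, 6))),
            }
        truth[outcome] = per_group
    manifest = {
        "n_subjects": n,
        "group_sizes": dict(config.group_sizes),
        "effects": truth,
    }
    return panels, manifest


def _phase_mass(
    subject_id: str,
    phase: int,
    config: TrialConfig,
    mass_panel: pd.DataFrame,
) -> float:
    tp = config.phase_mass_timepoint[phase]
    sel = mass_panel[
        (mass_panel["subject_id"] == subject_id) & (mass_panel["timepoint"] == tp)
    ]
    return float(sel["value"].iloc[0])


def gen_session(
    subject: Mapping,
    phase: int,
    rng: np.random.Generator,
    config: TrialConfig,
) -> SessionPhysiology:
    """Draw one monitored session's physiology for a subject and phase.

    Lactate ordering (mid and post above pre) and the mean <= max heart-rate
    constraint are enforced on every draw.
    """
    if phase not in config.phases:
        raise ValueError(f"unknown phase {phase}")
    p = config.phases[phase]
    k = config.trunc_sd
    mean_hr = _truncnorm(rng, *p["mean_hr"], lo=60, n_sd=k)
    max_hr = _truncnorm(rng, *p["max_hr"], lo=80, n_sd=k)
    max_hr = max(max_hr, mean_hr + 1.0)
    pre = _truncnorm(rng, *p["lactate_pre"], lo=0.3, n_sd=k)
    mid = max(_truncnorm(rng, *p["lactate_mid"], lo=0.5, n_sd=k), pre)
    post = max(_truncnorm(rng, *p["lactate_post"], lo=0.5, n_sd=k), pre)
    vo2 = _truncnorm(rng, *p["mean_vo2_mlkgmin"], lo=5, n_sd=k)
    ve = _truncnorm(rng, *p["ve_lmin"], lo=10, n_sd=k)
    rer = _truncnorm(rng, *p["rer"], lo=0.7, hi=1.3, n_sd=k)
    rpe = float(np.clip(_truncnorm(rng, *p["rpe"], n_sd=k), 6, 20))
    kcal_per_l = config.energy_constants().kcal_per_litre_o2
    epoc_kcal = _truncnorm(rng, *p["epoc_kcal"], lo=0.5, n_sd=k)
    return SessionPhysiology(
        phase=phase, mean_hr=mean_hr, max_hr=max_hr,
        lactate_pre=pre, lactate_mid=mid, lactate_post=post,
        mean_vo2=vo2, ve=ve, rer=rer, rpe=rpe,
        epoc_litres=epoc_kcal / kcal_per_l,
    )


def gen_sessions_frame(
    cohort: pd.DataFrame,
    mass_panel: pd.DataFrame,
    config: TrialConfig,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """One monitored session per training subject per phase, as a flat table."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for phase in sorted(config.phases):
        groups = set(config.phase_groups[phase])
        date = _START_DATE + pd.Timedelta(weeks={1: 3, 2: 10, 3: 17, 4: 30}[phase])
        for _, subj in cohort.iterrows():
            if subj["group"] not in groups:
                continue
            s = gen_session(subj, phase, rng, config)
            rows.append({
                "subject_id": subj["subject_id"],
                "phase": phase,
                "date": date.date().isoformat(),
                "mean_hr": round(s.mean_hr, 1),
                "max_hr": round(s.max_hr, 1),
                "lactate_pre": round(s.lactate_pre, 2),
                "lactate_mid": round(s.lactate_mid, 2),
                "lactate_post": round(s.lactate_post, 2),
                "mean_vo2_mlkgmin": round(s.mean_vo2, 2),
                "ve_lmin": round(s.ve, 1),
                "rer": round(s.rer, 3),
                "rpe": round(s.rpe, 1),
                "epoc_litres": round(s.epoc_litres, 3),
                "mass_kg": round(_phase_mass(subj["subject_id"], phase, config, mass_panel), 2),
            })
    return pd.DataFrame(rows)


def _two_state_minutes(
    n_min: int, p_active: float, rng: np.random.Generator, mean_active_run: float = 8.0
) -> np.ndarray:
    """Active/inactive minute labels from an alternating-run Markov chain."""
    if p_active <= 0:
        return np.zeros(n_min, dtype=bool)
    if p_active >= 1:
        return np.ones(n_min, dtype=bool)
    mean_inactive_run = mean_active_run * (1.0 - p_active) / p_active
    out = np.empty(n_min, dtype=bool)
    pos = 0
    state = bool(rng.random() < p_active)
    while pos < n_min:
        mean_run = mean_active_run if state else mean_inactive_run
        run = int(rng.geometric(min(1.0, 1.0 / max(mean_run, 1.0))))
        run = min(run, n_min - pos)
        out[pos : pos + run] = state
        pos += run
        state = not state
    return out


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def gen_accel_week(
    targets: Mapping[str, float],
    seed: int | np.random.Generator,
    days: int = 7,
    start: pd.Timestamp | None = None,
    nonwear_blocks: Sequence[tuple[int, int, int]] = (),
) -> pd.DataFrame:
    """Generate a week of 60-s epoch counts hitting daily activity targets.

    ``targets`` carries per-day band minutes (sedentary/light/moderate/
    vigorous, summing to at most 1440) and ``steps_day``.  ``nonwear_blocks``
    is a list of (day_index, start_minute, duration) all-zero blocks to
    insert.  Band-minute and step totals are unbiased for the targets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = _START_DATE if start is None else start
    light = float(targets.get("light_min", 0.0))
    mod = float(targets.get("moderate_min", 0.0))
    vig = float(targets.get("vigorous_min", 0.0))
    steps_target = float(targets.get("steps_day", 0.0))
    active_target = light + mod + vig
    if active_target > 1440:
        raise ValueError("band-minute targets exceed the day length")

    frames = []
    for d in range(days):
        blocks = [(s, dur) for (bd, s, dur) in nonwear_blocks if bd == d]
        nonwear = np.zeros(1440, dtype=bool)
        for s, dur in blocks:
            nonwear[s : s + dur] = True
        wear_min = int((~nonwear).sum())
        scale = wear_min / 1440.0
        if active_target * scale > wear_min:
            raise ValueError("activity target infeasible under the wear schedule")
        p_active = min(1.0, active_target * scale / max(wear_min, 1))

        active = _two_state_minutes(wear_min, p_active, rng)
        n_active = int(active.sum())
        vm = np.zeros(wear_min)
        band_probs = (
            np.array([light, mod, vig]) / active_target
            if active_target > 0
            else np.array([1.0, 0.0, 0.0])
        )
        band = rng.choice(3, size=n_active, p=band_probs)
        vm_active = np.empty(n_active)
        for b, (lo, hi) in enumerate([(200, 2689), (2690, 6166), (6167, 12000)]):
            m = band == b
            vm_active[m] = _loguniform(rng, lo, hi, int(m.sum()))
        vm[active] = vm_active
        inactive_idx = np.flatnonzero(~active)
        moving = rng.random(inactive_idx.size) > 0.35
        vm[inactive_idx[moving]] = _loguniform(rng, 1, 199, int(moving.sum()))

        # decompose vector magnitude onto three integer axes (vertical-biased)
        frac = rng.uniform(0.55, 0.80, size=wear_min)
        axis1 = np.round(vm * frac).astype(int)
        rest = np.sqrt(np.maximum(vm**2 - axis1**2, 0.0))
        theta = rng.uniform(0, np.pi / 2, size=wear_min)
        axis2 = np.round(rest * np.cos(theta)).astype(int)
        axis3 = np.round(rest * np.sin(theta)).astype(int)

        # steps: per-band Poisson rates rescaled so the expectation matches
        base_rate = np.zeros(wear_min)
        base_rate[active] = np.array([15.0, 105.0, 130.0])[band]
        expected = base_rate.sum()
        if expected > 0 and steps_target > 0:
            base_rate *= steps_target * scale / expected
        steps = rng.poisson(base_rate)

        full_axis = np.zeros((1440, 3), dtype=int)
        full_steps = np.zeros(1440, dtype=int)
        widx = np.flatnonzero(~nonwear)
        full_axis[widx, 0] = axis1
        full_axis[widx, 1] = axis2
        full_axis[widx, 2] = axis3
        full_steps[widx] = steps
        ts = start + pd.Timedelta(days=d) + pd.to_timedelta(np.arange(1440), unit="m")
        day = pd.DataFrame({
            "timestamp": ts,
            "axis1": full_axis[:, 0],
            "axis2": full_axis[:, 1],
            "axis3": full_axis[:, 2],
            "steps": full_steps,
        })
        day["vm"] = np.sqrt(
            day["axis1"] ** 2 + day["axis2"] ** 2 + day["axis3"] ** 2
        ).round(2)
        frames.append(day)
    return pd.concat(frames, ignore_index=True)


def gen_diet_week(
    target_kcal: float,
    macro_bands: Mapping[str, Sequence[float]],
    seed: int | np.random.Generator,
    day_noise_cv: float = 0.06,
    days: int = 7,
    start: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """A 7-day diet recall around an energy target.

    Daily energy is lognormal around the target (bias-corrected so the mean
    is the target); the macro split is drawn uniformly inside the
    prescription bands, rejecting draws whose fat remainder leaves its band.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = _START_DATE if start is None else start
    cho_lo, cho_hi = macro_bands["cho"]
    pro_lo, pro_hi = macro_bands["pro"]
    fat_lo, fat_hi = macro_bands["fat"]
    rows = []
    for d in range(days):
        kcal = target_kcal * float(
            np.exp(rng.normal(0.0, day_noise_cv) - day_noise_cv**2 / 2.0)
        )
        while True:
            cho = rng.uniform(cho_lo, cho_hi)
            pro = rng.uniform(pro_lo, pro_hi)
            fat = 100.0 - cho - pro
            if fat_lo <= fat <= fat_hi:
                break
        rows.append({
            "date": (start + pd.Timedelta(days=d)).date().isoformat(),
            "protein_g": round(kcal * pro / 100.0 / 4.0, 1),
            "carbohydrate_g": round(kcal * cho / 100.0 / 4.0, 1),
            "fat_g": round(kcal * fat / 100.0 / 9.0, 1),
        })
    df = pd.DataFrame(rows)
    df["energy_kcal"] = (
        4.0 * df["protein_g"] + 4.0 * df["carbohydrate_g"] + 9.0 * df["fat_g"]
    ).round(1)
    return df


def gen_panel(
    n_per_group: Sequence[int] = (21, 14, 14),
    effect_d: float = 0.0,
    icc: float = 0.7,
    n_timepoints: int = 3,
    seed: int | np.random.Generator = 0,
    group_names: Sequence[str] | None = None,
    timepoint_sds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Abstract outcome panel for statistical calibration.

    Unit total variance split into a subject random intercept (variance
    ``icc``) and residual noise; the first group is flat and every other
    group follows a linear slope reaching ``effect_d`` standardized units at
    the last timepoint.  ``timepoint_sds`` scales residual noise per
    timepoint to inject a sphericity violation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = list(group_names or ("C", "TR", "TRD")[: len(n_per_group)])
    tps = [f"t{j}" for j in range(n_timepoints)]
    sd_b = np.sqrt(icc)
    sd_e = np.sqrt(1.0 - icc)
    scales = np.ones(n_timepoints) if timepoint_sds is None else np.asarray(timepoint_sds)
    rows = []
    sid = 0
    for gi, (g, n) in enumerate(zip(groups, n_per_group)):
        slope = 0.0 if gi == 0 else effect_d
        for _ in range(n):
            b = rng.normal(0.0, sd_b)
            for j, tp in enumerate(tps):
                delta = slope * j / (n_timepoints - 1)
                e = rng.normal(0.0, sd_e * scales[j])
                rows.append({
                    "subject_id": f"P{sid:03d}", "group": g,
                    "timepoint": tp, "value": b + delta + e,
                })
            sid += 1
    return pd.DataFrame(rows)


def simulate_trial(
    config: TrialConfig | None,
    seed: int,
    out_dir: str | Path,
    accel_days: int = 7,
) -> dict:
    """Generate and write a full trial data set; returns the manifest.

    Writes subjects.csv, assessments.csv, sessions.csv, recalls.csv,
    attendance.csv, per-subject epoch CSVs under epochs/, and
    manifest.json with the ground truth.
    """
    config = config or load_trial_config()
    out = Path(out_dir)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_cohort, r_traj, r_sess, r_accel, r_diet, r_att = rngs

    cohort = gen_cohort(config, r_cohort)
    panels, manifest = gen_trajectories(cohort, config, r_traj)
    constants = config.energy_constants()

    # assessments: wide per subject-timepoint, with resting gas exchange that
    # reproduces the RMR trajectory through the Weir equation
    recs = []
    for tp in TIMEPOINTS:
        for i, subj in cohort.iterrows():
            sid = subj["subject_id"]
            row = {"subject_id": sid, "group": subj["group"], "timepoint": tp,
                   "height_m": round(subj["height_m"], 3)}
            for outcome in ALL_OUTCOMES:
                p = panels[outcome]
                v = p[(p["subject_id"] == sid) & (p["timepoint"] == tp)]["value"].iloc[0]
                row[outcome] = round(float(v), 3)
            rer = subj["rer_rest"]
            vo2 = row["rmr_kcal_day"] / ((constants.weir_a + constants.weir_b * rer) * 1440.0)
            row["resting_vo2_lmin"] = round(vo2, 5)
            row["resting_vco2_lmin"] = round(vo2 * rer, 5)
            row["resting_hr"] = round(subj["resting_hr"], 1)
            row["max_hr_test"] = round(subj["max_hr_test"], 1)
            recs.append(row)
    assessments = pd.DataFrame(recs)

    sessions = gen_sessions_frame(cohort, panels["body_mass_kg"], config, r_sess)

    recalls_frames = []
    epoch_files = []
    tp_offset = {"baseline": 0, "20wk": 20, "40wk": 40}
    for tp in TIMEPOINTS:
        week_start = _START_DATE + pd.Timedelta(weeks=tp_offset[tp])
        for _, subj in cohort.iterrows():
            sid, g = subj["subject_id"], subj["group"]
            accel = gen_accel_week(
                config.activity[g], r_accel, days=accel_days, start=week_start
            )
            fname = f"epochs/{sid}_{tp}.csv"
            accel.to_csv(out / fname, index=False)
            epoch_files.append(fname)
            diet = gen_diet_week(
                config.intake["target_kcal"][g],
                config.intake["macro_bands"],
                r_diet,
                day_noise_cv=config.intake.get("day_noise_cv", 0.06),
                start=week_start,
            )
            diet.insert(0, "timepoint", tp)
            diet.insert(0, "subject_id", sid)
            recalls_frames.append(diet)
    recalls = pd.concat(recalls_frames, ignore_index=True)

    att_rows = []
    for _, subj in cohort.iterrows():
        if subj["group"] == "C":
            continue
        total = 120 if subj["group"] == "TR" else 60  # 3 sessions/week
        attended = int(r_att.binomial(total, config.attendance_rate))
        att_rows.append({
            "subject_id": subj["subject_id"], "group": subj["group"],
            "sessions_attended": attended, "sessions_total": total,
        })
    attendance = pd.DataFrame(att_rows)

    cohort_out = cohort.copy()
    for c in cohort_out.columns:
        if cohort_out[c].dtype.kind == "f":
            cohort_out[c] = cohort_out[c].round(4)
    cohort_out.to_csv(out / "subjects.csv", index=False)
    assessments.to_csv(out / "assessments.csv", index=False)
    sessions.to_csv(out / "sessions.csv", index=False)
    recalls.to_csv(out / "recalls.csv", index=False)
    attendance.to_csv(out / "attendance.csv", index=False)

    manifest.update({
        "seed": seed,
        "config_version": config.version,
        "energy_constants": constants.model_dump(mode="json"),
        "activity_targets": config.activity,
        "intake_targets": config.intake["target_kcal"],
        "attendance_rate": config.attendance_rate,
        "files": ["subjects.csv", "assessments.csv", "sessions.csv",
                  "recalls.csv", "attendance.csv"] + epoch_files,
    })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
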