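"""End-to-end orchestration: input validation, per-stage processing and
report generation.

``run_pipeline`` consumes a directory of trial CSVs (assessments, monitored
sessions, accelerometer epoch files, diet recalls, optional attendance log),
runs the physiology, accelerometry, intake, ledger and statistics stages and
writes a JSON + markdown report bundle with an embedded run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accelerometry import read_epoch_csv, summarize_days, valid_wear_filter
from .config import StudyConfig
from .intake import DietRecallDay, mean_energy_intake
from .ledger import day_balance, period_fat_equivalent, week_balance
from .physiology import GasExchange, SessionPhysiology, session_energy, weir_rmr
from .stats import OutcomePanel, ancova_adjust, percent_change, rm_anova

__all__ = ["RunManifest", "validate_inputs", "run_pipeline", "compliance_rate"]

TIMEPOINTS = ("baseline", "20wk", "40wk")
OUTCOME_COLUMNS = (
    "body_mass_kg", "bmi", "body_fat_pct", "fat_mass_kg", "ffm_kg",
    "waist_cm", "hip_cm", "whr", "rmr_kcal_day", "vo2max_mlkgmin", "one_rm_kg",
)
#: session phase whose energy cost is booked on exercise days at each timepoint
PHASE_AT_TIMEPOINT = {"20wk": 3, "40wk": 4}
REQUIRED_FILES = ("assessments.csv", "sessions.csv", "recalls.csv")

SESSION_COLUMNS = [
    "subject_id", "phase", "mean_hr", "max_hr", "lactate_pre", "lactate_mid",
    "lactate_post", "mean_vo2_mlkgmin", "rpe", "epoc_litres",
]
RECALL_COLUMNS = ["subject_id", "date", "protein_g", "carbohydrate_g", "fat_g"]


@dataclass
class RunManifest:
    """Provenance block embedded in every report."""

    config_hash: str
    seed: int | None
    inputs: dict[str, str]
    package_version: str
    timestamp: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(files: list[str | Path]) -> list[dict]:
    """Schema-check input files without mutating anything.

    Returns one entry per file with status pass/warn/fail and the first
    offending row where applicable.  Unreadable files yield a fail entry,
    not an exception.
    """
    reports = []
    for f in files:
        path = Path(f)
        entry = {"file": str(path), "status": "pass", "detail": ""}
        try:
            if "epoch" in path.name or path.parent.name == "epochs":
                read_epoch_csv(path)
            elif path.name.startswith("recall") or "recall" in path.name:
                df = pd.read_csv(path)
                missing = [c for c in RECALL_COLUMNS if c not in df.columns]
                if missing:
                    raise ValueError(f"missing columns {missing}")
                for col in ("protein_g", "carbohydrate_g", "fat_g"):
                    bad = df.index[df[col] < 0]
                    if len(bad):
                        raise ValueError(f"negative {col} at row {int(bad[0])}")
                if "energy_kcal" in df.columns:
                    computed = (
                        4 * df["protein_g"] + 4 * df["carbohydrate_g"] + 9 * df["fat_g"]
                    )
                    off = (df["energy_kcal"] - computed).abs() > 0.05 * computed
                    if off.any():
                        entry["status"] = "warn"
                        entry["detail"] = (
                            f"energy_kcal deviates >5% from 4P+4C+9F at row "
                            f"{int(df.index[off][0])}"
                        )
            elif path.name.startswith("session"):
                df = pd.read_csv(path)
                missing = [c for c in SESSION_COLUMNS if c not in df.columns]
                if missing:
                    raise ValueError(f"missing columns {missing}")
                bad = df.index[df["mean_hr"] > df["max_hr"]]
                if len(bad):
                    raise ValueError(f"mean_hr > max_hr at row {int(bad[0])}")
                for col in ("lactate_pre", "lactate_mid", "lactate_post"):
                    bad = df.index[df[col] <= 0]
                    if len(bad):
                        raise ValueError(f"nonpositive {col} at row {int(bad[0])}")
            elif path.name.startswith("assessment"):
                df = pd.read_csv(path)
                needed = ["subject_id", "group", "timepoint", *OUTCOME_COLUMNS]
                missing = [c for c in needed if c not in df.columns]
                if missing:
                    raise ValueError(f"missing columns {missing}")
            else:
                pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            entry["status"] = "fail"
            entry["detail"] = str(exc)
        reports.append(entry)
    return reports


def compliance_rate(attendance: pd.DataFrame) -> float:
    """Attendance compliance in percent: sessions attended / scheduled."""
    total = attendance["sessions_total"].sum()
    if total == 0:
        raise ValueError("no scheduled sessions")
    return float(attendance["sessions_attended"].sum() / total * 100.0)


def _session_energies(
    sessions: pd.DataFrame,
    assessments: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Energy decomposition of every monitored session."""
    mass_map = {1: "baseline", 2: "20wk", 3: "20wk", 4: "40wk"}
    rows = []
    for _, r in sessions.iterrows():
        if "mass_kg" in sessions.columns and not pd.isna(r.get("mass_kg")):
            mass = float(r["mass_kg"])
        else:
            tp = mass_map[int(r["phase"])]
            sel = assessments[
                (assessments["subject_id"] == r["subject_id"])
                & (assessments["timepoint"] == tp)
            ]
            if sel.empty:
                continue
            mass = float(sel["body_mass_kg"].iloc[0])
        s = SessionPhysiology(
            phase=int(r["phase"]), mean_hr=r["mean_hr"], max_hr=r["max_hr"],
            lactate_pre=r["lactate_pre"], lactate_mid=r["lactate_mid"],
            lactate_post=r["lactate_post"], mean_vo2=r["mean_vo2_mlkgmin"],
            ve=r.get("ve_lmin"), rer=r.get("rer"), rpe=r["rpe"],
            epoc_litres=float(r["epoc_litres"]),
        )
        e = session_energy(s, mass, config.energy)
        rows.append({"subject_id": r["subject_id"], "phase": int(r["phase"]), **e})
    return pd.DataFrame(rows)


def run_pipeline(
    in_dir: str | Path,
    out_dir: str | Path,
    config: StudyConfig | None = None,
    seed: int | None = None,
    timestamp: str | None = None,
) -> dict:
    """Run the full analysis over a trial input directory.

    Returns the report dict; writes report.json, report.md, ledgers.csv and
    effects.json under ``out_dir``.  Missing required inputs raise a clean
    error listing them; wear-invalid subjects are excluded from activity
    summaries with their IDs logged in the report.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    config = config or StudyConfig()
    missing = [f for f in REQUIRED_FILES if not (in_dir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"input directory {in_dir} is missing required files: {missing}"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    assessments = pd.read_csv(in_dir / "assessments.csv")
    sessions = pd.read_csv(in_dir / "sessions.csv")
    recalls = pd.read_csv(in_dir / "recalls.csv")
    epoch_paths = sorted((in_dir / "epochs").glob("*.csv")) if (in_dir / "epochs").exists() else []

    inputs = {p.name: _sha256(in_dir / p.name) for p in map(Path, REQUIRED_FILES)}
    inputs.update({f"epochs/{p.name}": _sha256(p) for p in epoch_paths})

    # resting metabolic rate recomputed from gas exchange where available
    if {"resting_vo2_lmin", "resting_vco2_lmin"} <= set(assessments.columns):
        assessments["rmr_weir_kcal_day"] = [
            weir_rmr(GasExchange(vo2=v, vco2=c), weir_a=config.energy.weir_a,
                     weir_b=config.energy.weir_b)
            for v, c in zip(
                assessments["resting_vo2_lmin"], assessments["resting_vco2_lmin"]
            )
        ]
    else:
        assessments["rmr_weir_kcal_day"] = assessments["rmr_kcal_day"]

    energies = _session_energies(sessions, assessments, config)
    energy_by_phase = (
        energies.groupby("phase")[["aee_kcal", "anee_kcal", "epoc_kcal", "tee_kcal",
                                   "mets", "met_hours", "weekly_met_hours",
                                   "kcal_per_min"]]
        .agg(["mean", "std"])
        if not energies.empty else pd.DataFrame()
    )

    # accelerometry: per subject-timepoint activity summary
    activity_rows, wear_invalid = [], []
    for p in epoch_paths:
        sid, tp = p.stem.rsplit("_", 1)
        sel = assessments[
            (assessments["subject_id"] == sid) & (assessments["timepoint"] == tp)
        ]
        if sel.empty:
            continue
        mass = float(sel["body_mass_kg"].iloc[0])
        days = summarize_days(read_epoch_csv(p), mass, config.accel)
        retained, valid = valid_wear_filter(
            days, config.accel.min_valid_days, config.accel.min_wear_min
        )
        if not valid:
            wear_invalid.append(f"{sid}@{tp}")
            continue
        activity_rows.append({
            "subject_id": sid, "timepoint": tp,
            "wear_min": float(np.mean([d.wear_min for d in retained])),
            "steps_day": float(np.mean([d.steps for d in retained])),
            "sedentary_min": float(np.mean([d.sedentary_min for d in retained])),
            "light_min": float(np.mean([d.light_min for d in retained])),
            "moderate_min": float(np.mean([d.moderate_min for d in retained])),
            "vigorous_min": float(np.mean([d.vigorous_min for d in retained])),
            "mvpa_min": float(np.mean([d.mvpa_min for d in retained])),
            "activity_kcal": float(np.mean([d.activity_kcal for d in retained])),
            "mean_mets": float(np.mean([d.mean_mets for d in retained])),
        })
    activity = pd.DataFrame(
        activity_rows,
        columns=["subject_id", "timepoint", "wear_min", "steps_day",
                 "sedentary_min", "light_min", "moderate_min", "vigorous_min",
                 "mvpa_min", "activity_kcal", "mean_mets"],
    )

    # diet recalls: per subject-timepoint intake summary
    intake_rows = []
    group_cols = ["subject_id"] + (["timepoint"] if "timepoint" in recalls.columns else [])
    for key, sub in recalls.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        days = [
            DietRecallDay(
                date=r.get("date"), protein_g=r["protein_g"],
                carbohydrate_g=r["carbohydrate_g"], fat_g=r["fat_g"],
                energy_kcal=r.get("energy_kcal"),
            )
            for _, r in sub.iterrows()
        ]
        summary = mean_energy_intake(days, config.intake)
        intake_rows.append({
            "subject_id": key[0],
            "timepoint": key[1] if len(key) > 1 else None,
            "energy_kcal_day": summary.energy_kcal_day,
            "protein_pct": summary.protein_pct,
            "cho_pct": summary.cho_pct,
            "fat_pct": summary.fat_pct,
        })
    intake = pd.DataFrame(
        intake_rows,
        columns=["subject_id", "timepoint", "energy_kcal_day", "protein_pct",
                 "cho_pct", "fat_pct"],
    )

    # energy ledger per subject-timepoint
    ledger_rows = []
    for _, a in assessments.iterrows():
        sid, tp, group = a["subject_id"], a["timepoint"], a["group"]
        rmr = float(a["rmr_weir_kcal_day"])
        act = activity[(activity["subject_id"] == sid) & (activity["timepoint"] == tp)]
        ik = intake[(intake["subject_id"] == sid) & (intake["timepoint"] == tp)]
        if act.empty or ik.empty:
            continue
        act_kcal = float(act["activity_kcal"].iloc[0])
        in_kcal = float(ik["energy_kcal_day"].iloc[0])
        ex_kcal = 0.0
        phase = PHASE_AT_TIMEPOINT.get(tp)
        if phase is not None and group in ("TR", "TRD") and not energies.empty:
            sel = energies[
                (energies["subject_id"] == sid) & (energies["phase"] == phase)
            ]
            if not sel.empty:
                ex_kcal = float(sel["tee_kcal"].iloc[0])
        ex_day = day_balance(in_kcal, rmr, act_kcal, ex_kcal,
                             config.ledger.tef_fraction)
        rest_day = day_balance(in_kcal, rmr, act_kcal, 0.0,
                               config.ledger.tef_fraction)
        n_ex = config.ledger.exercise_days_per_week if ex_kcal > 0 else 0
        weekly = week_balance(ex_day, rest_day, n_ex)
        period = period_fat_equivalent(
            weekly * 20.0, 20.0, config.ledger.fat_energy_density_kcal_per_kg
        )
        ledger_rows.append({
            "subject_id": sid, "group": group, "timepoint": tp,
            "intake_kcal": in_kcal, "rmr_kcal": rmr, "activity_kcal": act_kcal,
            "exercise_kcal": ex_kcal,
            "exercise_day_balance": ex_day.balance_kcal,
            "nonexercise_day_balance": rest_day.balance_kcal,
            "weekly_balance_kcal": weekly,
            "period20wk_balance_kcal": period.total_balance_kcal,
            "period20wk_fat_equivalent_kg": period.fat_equivalent_kg,
        })
    ledgers = pd.DataFrame(ledger_rows)

    # statistics per outcome
    effects = {}
    panels = {}
    for outcome in OUTCOME_COLUMNS:
        long = assessments.rename(columns={outcome: "value"})[
            ["subject_id", "group", "timepoint", "value"]
        ]
        panel = OutcomePanel.from_long(long, outcome)
        panels[outcome] = panel
        effects[outcome] = rm_anova(panel, config.stats).to_dict()

    # ANCOVA on body mass, covariates = subject-mean intake and steps
    ancova = None
    if not intake.empty and not activity.empty:
        cov = (
            intake.groupby("subject_id")["energy_kcal_day"].mean().rename("kcal_day")
            .to_frame()
            .join(activity.groupby("subject_id")["steps_day"].mean())
            .reset_index()
        )
        try:
            res = ancova_adjust(panels["body_mass_kg"], cov)
            ancova = {
                "group_p": res["group_p"],
                "interaction_p": res["interaction_p"],
                "covariate_slopes": res["covariate_slopes"],
                "collinear_covariates": res["collinear_covariates"],
                "adjusted_means": res["adjusted_means"].round(3).to_dict(),
            }
        except ValueError:
            ancova = None

    compliance = None
    if (in_dir / "attendance.csv").exists():
        compliance = compliance_rate(pd.read_csv(in_dir / "attendance.csv"))

    # headline percent changes from group means
    cell = {
        o: assessments.groupby(["group", "timepoint"])[o].mean().unstack()
        for o in OUTCOME_COLUMNS
    }
    pct = {}
    for o, tab in cell.items():
        pct[o] = {
            g: {
                "mid": percent_change(tab.loc[g, "baseline"], tab.loc[g, "20wk"]),
                "post": percent_change(tab.loc[g, "baseline"], tab.loc[g, "40wk"]),
            }
            for g in tab.index
        }

    manifest = RunManifest(
        config_hash=config.config_hash(), seed=seed, inputs=inputs,
        package_version=__version__, timestamp=timestamp,
    )
    report = {
        "manifest": manifest.to_dict(),
        "n_subjects": int(assessments["subject_id"].nunique()),
        "wear_invalid": wear_invalid,
        "compliance_pct": compliance,
        "session_energy_by_phase": (
            {
                str(ph): {
                    f"{m}_{s}": round(float(energy_by_phase.loc[ph, (m, s)]), 3)
                    for m, s in energy_by_phase.columns
                }
                for ph in energy_by_phase.index
            }
            if len(energy_by_phase) else {}
        ),
        "group_means": {
            o: {g: {tp: round(float(cell[o].loc[g, tp]), 3) for tp in TIMEPOINTS}
                for g in cell[o].index}
            for o in OUTCOME_COLUMNS
        },
        "percent_change": {
            o: {g: {k: round(v, 2) for k, v in d.items()} for g, d in per.items()}
            for o, per in pct.items()
        },
        "ledger_group_means": (
            {
                g: {
                    tp: {
                        c: round(float(v), 1)
                        for c, v in sub.drop(columns=["subject_id", "group", "timepoint"])
                        .mean().items()
                    }
                    for tp, sub in gsub.groupby("timepoint")
                }
                for g, gsub in ledgers.groupby("group")
            }
            if not ledgers.empty else {}
        ),
        "effects": effects,
        "ancova_body_mass": ancova,
    }

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out_dir / "effects.json").write_text(json.dumps(effects, indent=2, default=float))
    if not ledgers.empty:
        ledgers.round(2).to_csv(out_dir / "ledgers.csv", index=False)
    (out_dir / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# Trial analysis report", ""]
    m = report["manifest"]
    lines += [f"config hash: `{m['config_hash'][:12]}`; package {m['package_version']}", ""]
    if report.get("compliance_pct") is not None:
        lines += [f"Training compliance: {report['compliance_pct']:.1f}%", ""]
    if report["wear_invalid"]:
        lines += ["Wear-invalid subject-timepoints excluded: "
                  + ", ".join(report["wear_invalid"]), ""]
    if report["session_energy_by_phase"]:
        lines += ["## Session energy by phase", "",
                  "| phase | TEE (kcal) | AEE | ANEE | EPOC | METs | kcal/min |",
                  "|---|---|---|---|---|---|---|"]
        for ph, e in report["session_energy_by_phase"].items():
            lines.append(
                f"| {ph} | {e['tee_kcal_mean']:.1f} ± {e['tee_kcal_std']:.1f} "
                f"| {e['aee_kcal_mean']:.1f} | {e['anee_kcal_mean']:.1f} "
                f"| {e['epoc_kcal_mean']:.1f} | {e['mets_mean']:.2f} "
                f"| {e['kcal_per_min_mean']:.1f} |"
            )
        lines.append("")
    lines += ["## Outcomes (group means)", "",
              "| outcome | group | baseline | 20wk | 40wk | interaction p |",
              "|---|---|---|---|---|---|"]
    for o, per in report["group_means"].items():
        p_int = report["effects"][o]["interaction_p"]
        for g, tps in per.items():
            lines.append(
                f"| {o} | {g} | {tps['baseline']:.2f} | {tps['20wk']:.2f} "
                f"| {tps['40wk']:.2f} | {p_int:.2g} |"
            )
    lines.append("")
    if report["ledger_group_means"]:
        lines += ["## Energy ledger (group means)", "",
                  "| group | timepoint | exercise-day bal | rest-day bal | weekly |",
                  "|---|---|---|---|---|"]
        for g, tps in report["ledger_group_means"].items():
            for tp, e in tps.items():
                lines.append(
                    f"| {g} | {tp} | {e['exercise_day_balance']:.0f} "
                    f"| {e['nonexercise_day_balance']:.0f} "
                    f"| {e['weekly_balance_kcal']:.0f} |"
                )
        lines.append("")
    return "\n".join(lines)
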