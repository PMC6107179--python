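"""Synthetic-trial generator: determinism, calibration, round-trip fidelity."""

import numpy as np
import pandas as pd
import pytest

from ergotrial import simulate as sim
from ergotrial.accelerometry import detect_nonwear, summarize_days
from ergotrial.physiology import session_energy


class TestCohort:
    def test_deterministic(self, trial_config):
        a = sim.gen_cohort(trial_config, 5)
        b = sim.gen_cohort(trial_config, 5)
        pd.testing.assert_frame_equal(a, b)

    def test_large_cohort_moments(self, trial_config):
        cfg = trial_config.model_copy(
            update={"group_sizes": {"C": 1000, "TR": 1000, "TRD": 1000}}
        )
        cohort = sim.gen_cohort(cfg, 0)
        for g in ("C", "TR", "TRD"):
            mean, sd = cfg.baseline[g]["body_mass_kg"]
            got = cohort.loc[cohort.group == g, "body_mass_kg"].mean()
            assert got == pytest.approx(mean, abs=2 * sd / np.sqrt(1000))

    def test_bmi_inclusion_window(self, trial_config):
        cfg = trial_config.model_copy(
            update={"group_sizes": {"C": 400, "TR": 400, "TRD": 400}}
        )
        cohort = sim.gen_cohort(cfg, 3)
        bmi = cohort["body_mass_kg"] / cohort["height_m"] ** 2
        assert (bmi.between(25.1, 34.9)).mean() >= 0.99

    def test_body_composition_identity(self, trial_config):
        cohort = sim.gen_cohort(trial_config, 8)
        assert np.allclose(
            cohort["fat_mass_kg"] + cohort["ffm_kg"], cohort["body_mass_kg"]
        )

    def test_impossible_truncation_errors(self, trial_config):
        bad = {g: dict(v) for g, v in trial_config.baseline.items()}
        bad["C"] = dict(bad["C"], bmi=(50.0, 1.0))  # outside the BMI window
        cfg = trial_config.model_copy(update={"baseline": bad})
        with pytest.raises(ValueError, match="truncation"):
            sim.gen_cohort(cfg, 0)


class TestSessions:
    def test_lactate_ordering_every_draw(self, trial_config):
        rng = np.random.default_rng(1)
        for phase in (1, 2, 3, 4):
            for _ in range(100):
                s = sim.gen_session({}, phase, rng, trial_config)
                assert s.lactate_mid >= s.lactate_pre
                assert s.lactate_post >= s.lactate_pre
                assert s.mean_hr <= s.max_hr
                assert 6 <= s.rpe <= 20

    def test_phase1_lactate_levels(self, trial_config):
        rng = np.random.default_rng(2)
        draws = [sim.gen_session({}, 1, rng, trial_config) for _ in range(300)]
        assert np.mean([s.lactate_pre for s in draws]) == pytest.approx(1.61, abs=0.1)
        assert np.mean([s.lactate_post for s in draws]) == pytest.approx(8.99, abs=0.2)

    def test_configured_means_monotone_phases_1_to_3(self, trial_config):
        hr = [trial_config.phases[p]["mean_hr"][0] for p in (1, 2, 3)]
        vo2 = [trial_config.phases[p]["mean_vo2_mlkgmin"][0] for p in (1, 2, 3)]
        assert hr == sorted(hr) and vo2 == sorted(vo2)

    def test_phase2_energy_round_trip(self, trial_config):
        # generated phase-2 sessions fed through the energy chain reproduce
        # the reference session total within 5%
        rng = np.random.default_rng(3)
        constants = trial_config.energy_constants()
        mass = (
            trial_config.baseline["TR"]["body_mass_kg"][0]
            * trial_config.effects["body_mass_kg"]["TR"][0]
        )
        tees = [
            session_energy(sim.gen_session({}, 2, rng, trial_config), mass,
                           constants)["tee_kcal"]
            for _ in range(500)
        ]
        assert np.mean(tees) == pytest.approx(326.8, rel=0.05)

    def test_unknown_phase_rejected(self, trial_config):
        with pytest.raises(ValueError):
            sim.gen_session({}, 9, np.random.default_rng(0), trial_config)


class TestAccelWeek:
    def test_zero_activity_targets(self):
        df = sim.gen_accel_week(
            {"light_min": 0, "moderate_min": 0, "vigorous_min": 0, "steps_day": 0},
            seed=0, days=1,
        )
        assert (df["vm"] <= 199).all()
        assert df["steps"].sum() == 0

    def test_targets_recovered_by_analysis(self, trial_config):
        rng = np.random.default_rng(4)
        t = trial_config.activity["TR"]
        steps, mvpa = [], []
        for _ in range(12):
            week = sim.gen_accel_week(t, rng)
            days = summarize_days(week, 78.0)
            steps += [d.steps for d in days]
            mvpa += [d.mvpa_min for d in days]
        assert np.mean(steps) == pytest.approx(t["steps_day"], rel=0.10)
        assert np.mean(mvpa) == pytest.approx(
            t["moderate_min"] + t["vigorous_min"], rel=0.10
        )

    def test_inserted_nonwear_blocks_recovered(self, trial_config):
        week = sim.gen_accel_week(
            trial_config.activity["C"], seed=6, days=2,
            nonwear_blocks=[(0, 300, 120), (1, 600, 150)],
        )
        wear = detect_nonwear(week)
        assert not wear[300:420].any()          # day 0 block, full sensitivity
        assert not wear[1440 + 600 : 1440 + 750].any()
        # habitual sedentary minutes do not masquerade as non-wear
        assert wear[:300].mean() > 0.95

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            sim.gen_accel_week(
                {"light_min": 1200, "moderate_min": 300, "vigorous_min": 10,
                 "steps_day": 1000},
                seed=0, days=1,
            )

    def test_vm_dominates_axes(self, trial_config):
        week = sim.gen_accel_week(trial_config.activity["C"], seed=7, days=1)
        for ax in ("axis1", "axis2", "axis3"):
            assert (week["vm"] >= week[ax] - 0.51).all()


class TestDietWeek:
    def test_zero_noise_gives_constant_days(self, trial_config):
        df = sim.gen_diet_week(1840.5, trial_config.intake["macro_bands"],
                               seed=0, day_noise_cv=0.0)
        assert df["energy_kcal"].max() - df["energy_kcal"].min() < 40  # macro jitter only
        assert df["energy_kcal"].mean() == pytest.approx(1840.5, rel=0.01)

    def test_mean_on_target_across_replicates(self, trial_config):
        rng = np.random.default_rng(8)
        means = [
            sim.gen_diet_week(1840.5, trial_config.intake["macro_bands"], rng)
            ["energy_kcal"].mean()
            for _ in range(200)
        ]
        assert np.mean(means) == pytest.approx(1840.5, rel=0.03)

    def test_weeks_pass_prescription(self, trial_config):
        from ergotrial.intake import (
            DietRecallDay, PrescriptionBands, mean_energy_intake,
            prescription_check,
        )

        rng = np.random.default_rng(9)
        bands = PrescriptionBands(target_kcal=1840.5)
        passes = 0
        n = 100
        for _ in range(n):
            df = sim.gen_diet_week(1840.5, trial_config.intake["macro_bands"], rng)
            days = [
                DietRecallDay(protein_g=r.protein_g, carbohydrate_g=r.carbohydrate_g,
                              fat_g=r.fat_g)
                for r in df.itertuples()
            ]
            passes += prescription_check(mean_energy_intake(days), bands)["all_pass"]
        assert passes / n >= 0.95


class TestTrajectories:
    def test_missing_outcome_in_profile_rejected(self, trial_config):
        effects = dict(trial_config.effects)
        effects.pop("vo2max_mlkgmin")
        with pytest.raises(ValueError, match="missing outcome"):
            trial_config.model_copy(update={"effects": effects}).model_validate(
                trial_config.model_copy(update={"effects": effects}).model_dump()
            )

    def test_trained_gain_matches_design(self, trial_config):
        cohort = sim.gen_cohort(trial_config, 10)
        panels, _ = sim.gen_trajectories(cohort, trial_config, 11)
        p = panels["vo2max_mlkgmin"]
        tr = p[p.group == "TR"].pivot(index="subject_id", columns="timepoint",
                                      values="value")
        pct = (tr["40wk"].mean() / tr["baseline"].mean() - 1) * 100
        # within 2 SE of the configured +26.8% gain
        se = 2 * tr["40wk"].std() / tr["baseline"].mean() / np.sqrt(len(tr)) * 100
        assert pct == pytest.approx(26.8, abs=2 * se)

    def test_partial_detraining_regression_pattern(self, trial_config):
        cohort = sim.gen_cohort(trial_config, 12)
        _, manifest = sim.gen_trajectories(cohort, trial_config, 13)
        for outcome in ("vo2max_mlkgmin", "one_rm_kg", "rmr_kcal_day"):
            mid, post = manifest["effects"][outcome]["TRD"]["multipliers"]
            assert mid > post > 1.0  # gains regress but stay above baseline

    def test_derived_outcomes_consistent(self, trial_config):
        cohort = sim.gen_cohort(trial_config, 14)
        panels, _ = sim.gen_trajectories(cohort, trial_config, 15)
        mass = panels["body_mass_kg"].set_index(["subject_id", "timepoint"])["value"]
        fat = panels["fat_mass_kg"].set_index(["subject_id", "timepoint"])["value"]
        ffm = panels["ffm_kg"].set_index(["subject_id", "timepoint"])["value"]
        assert np.allclose(fat + ffm, mass)

    def test_null_profile_gives_null_interaction(self, trial_config):
        effects = {
            k: (dict(v) if v.get("derived") else
                {g: [1.0, 1.0] for g in ("C", "TR", "TRD")} | {"noise_cv": v["noise_cv"]})
            for k, v in trial_config.effects.items()
        }
        cfg = trial_config.model_copy(update={"effects": effects})
        cohort = sim.gen_cohort(cfg, 16)
        panels, manifest = sim.gen_trajectories(cohort, cfg, 17)
        from ergotrial.stats import OutcomePanel, rm_anova

        rep = rm_anova(OutcomePanel.from_long(panels["body_mass_kg"], "mass"),
                       with_posthoc=False)
        assert rep.interaction_p > 0.01
        for g in ("C", "TR", "TRD"):
            assert manifest["effects"]["body_mass_kg"][g]["configured"] == [1.0, 1.0]


def test_simulate_trial_bundle(tmp_path, trial_config):
    cfg = trial_config.model_copy(update={"group_sizes": {"C": 3, "TR": 3, "TRD": 3}})
    manifest = sim.simulate_trial(cfg, 99, tmp_path, accel_days=2)
    for f in ("subjects.csv", "assessments.csv", "sessions.csv", "recalls.csv",
              "attendance.csv", "manifest.json"):
        assert (tmp_path / f).exists()
    assert len(list((tmp_path / "epochs").glob("*.csv"))) == 9 * 3
    a = pd.read_csv(tmp_path / "assessments.csv")
    assert set(a["timepoint"]) == {"baseline", "20wk", "40wk"}
    # resting gas reproduces the assessed RMR through the Weir equation
    back = (3.941 * a["resting_vo2_lmin"] + 1.106 * a["resting_vco2_lmin"]) * 1440
    assert np.allclose(back, a["rmr_kcal_day"], rtol=0.002)
    assert manifest["group_sizes"] == {"C": 3, "TR": 3, "TRD": 3}
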