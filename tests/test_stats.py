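"""Trial statistics: ANOVA vs an explicit sums-of-squares oracle, effect
sizes, post-hoc family, ANCOVA adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ergotrial.config import StatsConstants
from ergotrial.simulate import gen_panel
from ergotrial.stats import (
    OutcomePanel,
    ancova_adjust,
    bonferroni,
    hedges_g,
    interpret_es,
    percent_change,
    rm_anova,
)
from tests._oracles import splitplot_f_oracle


def _panel(df, name="y"):
    return OutcomePanel.from_long(df, name)


class TestRmAnova:
    def test_constant_values_give_null_result(self):
        df = gen_panel((4, 4), seed=0)
        df["value"] = 5.0
        rep = rm_anova(_panel(df), with_posthoc=False)
        assert rep.interaction_f == 0.0 and rep.interaction_p == 1.0
        assert rep.group_f == 0.0 and rep.group_p == 1.0

    @pytest.mark.parametrize("shape,seed", [((4, 4, 4), 10), ((5, 5, 5), 11),
                                            ((4, 4), 12)])
    def test_matches_sums_of_squares_oracle(self, shape, seed):
        df = gen_panel(shape, effect_d=0.6, icc=0.5, seed=seed)
        rep = rm_anova(_panel(df), with_posthoc=False)
        f_group, f_time, f_inter = splitplot_f_oracle(df)
        assert rep.group_f == pytest.approx(f_group, abs=1e-8)
        assert rep.time_f == pytest.approx(f_time, abs=1e-8)
        assert rep.interaction_f == pytest.approx(f_inter, abs=1e-8)

    def test_requires_two_groups_and_timepoints(self):
        df = gen_panel((4,), group_names=["C"], seed=0)
        with pytest.raises(ValueError):
            rm_anova(_panel(df))

    def test_incomplete_subjects_dropped(self):
        df = gen_panel((4, 4), seed=1)
        df = df[~((df["subject_id"] == "P000") & (df["timepoint"] == "t2"))]
        panel = _panel(df)
        assert panel.n_dropped == 1
        assert panel.data["subject_id"].nunique() == 7

    def test_gg_correction_raises_p_when_forced(self):
        df = gen_panel((8, 8), effect_d=0.5, seed=4, timepoint_sds=(0.4, 1.0, 2.0))
        cond = rm_anova(_panel(df), StatsConstants(gg_mode="conditional"),
                        with_posthoc=False)
        always = rm_anova(_panel(df), StatsConstants(gg_mode="always"),
                          with_posthoc=False)
        assert always.gg_applied
        assert 1 / 2 < always.gg_epsilon <= 1.0
        # corrected dfs are the raw dfs scaled by epsilon, and the reported p
        # is recomputed from the F distribution at those dfs
        from scipy import stats as sps

        eps = always.gg_epsilon
        assert always.df_corrected["time"] == pytest.approx(
            tuple(eps * d for d in always.df_raw["time"])
        )
        assert always.interaction_p == pytest.approx(
            float(sps.f.sf(always.interaction_f, *always.df_corrected["interaction"]))
        )
        assert cond.df_raw["time"][0] == 2.0

    def test_detects_true_interaction_with_adequate_power(self):
        # a d=1.0 slope difference at trial-like group sizes should be
        # detected in the vast majority of replicates
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            df = gen_panel((21, 14, 14), effect_d=1.0, icc=0.7, seed=rng)
            rep = rm_anova(_panel(df), with_posthoc=False)
            hits += rep.interaction_p < 0.05
        assert hits / n_rep >= 0.85


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], 3)[0] == pytest.approx(0.03)
        assert bonferroni([0.5], 3)[0] == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_adjusted_at_least_raw_and_order_preserving(self, ps):
        adj = bonferroni(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestHedgesG:
    def test_zero_difference(self):
        out = hedges_g(10, 2, 14, 10, 2, 14)
        assert out["g"] == 0.0
        assert out["ci_low"] == pytest.approx(-out["ci_high"])

    def test_hand_arithmetic(self):
        out = hedges_g(10, 2, 14, 12, 2, 14)
        assert out["g"] == pytest.approx(-0.971, abs=0.001)

    def test_tabulated_phase_contrast_diverges(self):
        # tabulated phase-1 vs phase-2 mean-HR effect size is -1.14; the
        # standard pooled bias-corrected formula gives about -1.08 from the
        # same printed means/SDs -- reported, not silently matched
        out = hedges_g(118.5, 9.2, 14, 130.8, 12.6, 14)
        assert out["g"] == pytest.approx(-1.08, abs=0.01)
        assert abs(out["g"] - (-1.14)) > 0.03

    def test_antisymmetry(self):
        a = hedges_g(10, 2, 12, 13, 3, 9)
        b = hedges_g(13, 3, 9, 10, 2, 12)
        assert a["g"] == pytest.approx(-b["g"])

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    def test_affine_invariance(self, scale, shift):
        base = hedges_g(10, 2, 12, 13, 3, 9)["g"]
        moved = hedges_g(10 * scale + shift, 2 * scale, 12,
                         13 * scale + shift, 3 * scale, 9)["g"]
        assert abs(moved) == pytest.approx(abs(base), rel=1e-6)

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError):
            hedges_g(10, 0, 14, 12, 2, 14)


class TestInterpretEs:
    @pytest.mark.parametrize("g,band", [
        (0.0, "none"), (0.19, "none"), (0.20, "small"), (-0.49, "small"),
        (0.50, "medium"), (-0.61, "medium"), (0.79, "medium"),
        (0.80, "large"), (0.85, "large"), (-3.0, "large"),
    ])
    def test_band_edges(self, g, band):
        assert interpret_es(g) == band

    def test_dense_grid_exhaustive_and_exclusive(self):
        for g in np.linspace(-2.5, 2.5, 2001):
            band = interpret_es(float(g))
            a = abs(g)
            expected = (
                "none" if a < 0.2 else "small" if a < 0.5
                else "medium" if a < 0.8 else "large"
            )
            assert band == expected


class TestAncova:
    def test_zero_slope_covariate_leaves_means_unchanged(self):
        import warnings as w

        df = gen_panel((5, 5), effect_d=0.8, seed=7)
        subjects = df["subject_id"].unique()
        # constant covariate: its centred column is identically zero, so the
        # fitted slope is exactly zero and adjusted means equal raw means
        cov = pd.DataFrame({"subject_id": subjects,
                            "kcal_day": np.full(len(subjects), 1800.0)})
        with w.catch_warnings():
            w.simplefilter("ignore")
            res = ancova_adjust(_panel(df), cov)
        pd.testing.assert_frame_equal(
            res["adjusted_means"], res["raw_means"], check_exact=False, atol=1e-8
        )

    def test_known_slope_matches_normal_equations(self):
        rng = np.random.default_rng(21)
        df = gen_panel((6, 6), effect_d=0.5, seed=22)
        subjects = pd.Index(df["subject_id"].unique())
        z = rng.normal(size=len(subjects))
        cov = pd.DataFrame({"subject_id": subjects, "z": z})
        zmap = dict(zip(subjects, z))
        df["value"] = df["value"] + 2.5 * df["subject_id"].map(zmap)
        res = ancova_adjust(_panel(df), cov)
        # slope recovered within sampling error of the 12-subject design
        assert res["covariate_slopes"]["z"] == pytest.approx(2.5, abs=0.9)

        # independent normal-equations solution of the same linear model
        d = df.merge(cov, on="subject_id")
        cells = sorted(zip(d["group"], d["timepoint"]))
        cell_index = {c: i for i, c in enumerate(dict.fromkeys(cells))}
        X = np.zeros((len(d), len(cell_index) + 1))
        for r, (g, t) in enumerate(zip(d["group"], d["timepoint"])):
            X[r, cell_index[(g, t)]] = 1.0
        X[:, -1] = d["z"] - d["z"].mean()
        beta, *_ = np.linalg.lstsq(X, d["value"].to_numpy(), rcond=None)
        for (g, t), i in cell_index.items():
            assert res["adjusted_means"].loc[g, t] == pytest.approx(
                beta[i], abs=1e-6
            )

    def test_collinear_covariates_flagged(self):
        df = gen_panel((5, 5), seed=9)
        subjects = pd.Index(df["subject_id"].unique())
        z = np.arange(len(subjects), dtype=float)
        cov = pd.DataFrame({"subject_id": subjects, "a": z, "b": 2 * z + 1})
        res = ancova_adjust(_panel(df), cov)
        assert res["collinear_covariates"]


class TestPercentChange:
    @pytest.mark.parametrize("pre,post,expected", [
        (26.1, 33.1, 26.8), (124.6, 158.5, 27.2), (10.0, 10.0, 0.0),
    ])
    def test_examples(self, pre, post, expected):
        assert percent_change(pre, post) == pytest.approx(expected, abs=0.05)

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)


def test_posthoc_family(trial_config):
    df = gen_panel((6, 6, 6), effect_d=1.2, seed=30)
    rep = rm_anova(_panel(df))
    ph = rep.posthoc
    # 3 group pairs x 3 timepoints + 3 timepoint pairs x 3 groups = 18
    assert len(ph) == 18
    assert (ph["p_adj"] >= ph["p_raw"] - 1e-12).all()
    assert set(ph["kind"]) == {"between", "within"}
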