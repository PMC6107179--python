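"""Trial statistics for 3-group x 3-timepoint outcomes.

Mixed (split-plot) repeated-measures ANOVA — group between, time within —
with Mauchly's sphericity test and conditional Greenhouse-Geisser df
correction; Bonferroni-adjusted post-hoc contrasts; bias-corrected Hedge's g
with 95% confidence interval and magnitude band; covariate (ANCOVA)
adjustment of group x time means; percent change.

The ANOVA/sphericity machinery is delegated to pingouin; effect sizes and
the post-hoc family are computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .config import StatsConstants

__all__ = [
    "OutcomePanel",
    "EffectReport",
    "rm_anova",
    "bonferroni",
    "hedges_g",
    "interpret_es",
    "ancova_adjust",
    "percent_change",
    "posthoc_table",
]

GROUPS = ("C", "TR", "TRD")
TIMEPOINTS = ("baseline", "20wk", "40wk")


@dataclass
class OutcomePanel:
    """Complete-case long-format panel of one outcome.

    Records carry subject_id, group, timepoint and value.  Subjects missing
    any timepoint are dropped on construction (complete-case analysis) and
    counted in ``n_dropped``.
    """

    data: pd.DataFrame
    outcome: str = "outcome"
    n_dropped: int = 0

    @classmethod
    def from_long(cls, df: pd.DataFrame, outcome: str = "outcome") -> "OutcomePanel":
        required = {"subject_id", "group", "timepoint", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel missing columns {sorted(missing)}")
        df = df.dropna(subset=["value"]).copy()
        n_tp = df["timepoint"].nunique()
        counts = df.groupby("subject_id")["timepoint"].nunique()
        complete = counts.index[counts == n_tp]
        n_dropped = int(df["subject_id"].nunique() - len(complete))
        if n_dropped:
            warnings.warn(
                f"{n_dropped} incomplete subject(s) dropped from panel "
                f"'{outcome}' (complete-case analysis)",
                stacklevel=2,
            )
        df = df[df["subject_id"].isin(complete)]
        sizes = df.groupby("group")["subject_id"].nunique()
        if (sizes < 2).any():
            raise ValueError("each group needs at least 2 complete subjects")
        return cls(data=df.reset_index(drop=True), outcome=outcome, n_dropped=n_dropped)

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    @property
    def timepoints(self) -> list[str]:
        order = [t for t in TIMEPOINTS if t in set(self.data["timepoint"])]
        extras = [t for t in self.data["timepoint"].unique() if t not in order]
        return order + sorted(extras)

    def cell_means(self) -> pd.DataFrame:
        return (
            self.data.groupby(["group", "timepoint"])["value"].mean().unstack()
        )


@dataclass
class EffectReport:
    """ANOVA core, sphericity diagnostics and post-hoc results for one outcome."""

    outcome: str
    anova: pd.DataFrame
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    gg_applied: bool
    interaction_f: float
    interaction_p: float
    time_f: float
    time_p: float
    group_f: float
    group_p: float
    df_raw: dict[str, tuple[float, float]] = field(default_factory=dict)
    df_corrected: dict[str, tuple[float, float]] = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None
    n_dropped: int = 0

    def to_dict(self) -> dict:
        out = {
            "outcome": self.outcome,
            "group_f": self.group_f, "group_p": self.group_p,
            "time_f": self.time_f, "time_p": self.time_p,
            "interaction_f": self.interaction_f, "interaction_p": self.interaction_p,
            "mauchly_w": self.mauchly_w, "mauchly_p": self.mauchly_p,
            "gg_epsilon": self.gg_epsilon, "gg_applied": self.gg_applied,
            "df_raw": {k: list(v) for k, v in self.df_raw.items()},
            "df_corrected": {k: list(v) for k, v in self.df_corrected.items()},
            "n_dropped": self.n_dropped,
        }
        if self.posthoc is not None:
            out["posthoc"] = self.posthoc.to_dict(orient="records")
        return out


def rm_anova(
    panel: OutcomePanel,
    constants: StatsConstants | None = None,
    with_posthoc: bool = True,
) -> EffectReport:
    """Two-way (group x time) mixed repeated-measures ANOVA.

    Mauchly's test is run on the within factor; when its p falls below alpha
    (or always, in ``gg_mode='always'``) the within and interaction degrees
    of freedom are multiplied by the Greenhouse-Geisser epsilon and p-values
    recomputed from the corrected F distribution.
    """
    c = constants or StatsConstants()
    df = panel.data
    if df["group"].nunique() < 2 or df["timepoint"].nunique() < 2:
        raise ValueError("need at least 2 groups and 2 timepoints")

    if np.ptp(df["value"].to_numpy()) == 0:
        # degenerate panel: no variance anywhere
        k = df["timepoint"].nunique()
        n = df["subject_id"].nunique()
        g = df["group"].nunique()
        dfs = {
            "group": (g - 1.0, float(n - g)),
            "time": (k - 1.0, float((n - g) * (k - 1))),
            "interaction": (float((g - 1) * (k - 1)), float((n - g) * (k - 1))),
        }
        return EffectReport(
            outcome=panel.outcome, anova=pd.DataFrame(),
            mauchly_w=1.0, mauchly_p=1.0, gg_epsilon=1.0, gg_applied=False,
            interaction_f=0.0, interaction_p=1.0, time_f=0.0, time_p=1.0,
            group_f=0.0, group_p=1.0, df_raw=dfs, df_corrected=dfs,
            posthoc=None, n_dropped=panel.n_dropped,
        )

    aov = pg.mixed_anova(
        data=df, dv="value", within="timepoint", subject="subject_id",
        between="group", correction=True,
    ).set_index("Source")
    sph = pg.sphericity(df, dv="value", within="timepoint", subject="subject_id")
    eps = float(aov.loc["timepoint", "eps"])
    row_g, row_t, row_i = aov.loc["group"], aov.loc["timepoint"], aov.loc["Interaction"]

    df_raw = {
        "group": (float(row_g["DF1"]), float(row_g["DF2"])),
        "time": (float(row_t["DF1"]), float(row_t["DF2"])),
        "interaction": (float(row_i["DF1"]), float(row_i["DF2"])),
    }
    apply_gg = c.gg_mode == "always" or (float(sph.pval) < c.alpha)
    df_corr = dict(df_raw)
    time_p = float(row_t["p_unc"])
    inter_p = float(row_i["p_unc"])
    if apply_gg:
        df_corr["time"] = (df_raw["time"][0] * eps, df_raw["time"][1] * eps)
        df_corr["interaction"] = (
            df_raw["interaction"][0] * eps, df_raw["interaction"][1] * eps,
        )
        time_p = float(sps.f.sf(row_t["F"], *df_corr["time"]))
        inter_p = float(sps.f.sf(row_i["F"], *df_corr["interaction"]))

    posthoc = posthoc_table(panel) if with_posthoc else None
    return EffectReport(
        outcome=panel.outcome,
        anova=aov.reset_index(),
        mauchly_w=float(sph.W),
        mauchly_p=float(sph.pval),
        gg_epsilon=eps,
        gg_applied=apply_gg,
        interaction_f=float(row_i["F"]), interaction_p=inter_p,
        time_f=float(row_t["F"]), time_p=time_p,
        group_f=float(row_g["F"]), group_p=float(row_g["p_unc"]),
        df_raw=df_raw, df_corrected=df_corr,
        posthoc=posthoc, n_dropped=panel.n_dropped,
    )


def bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m*p); m defaults to the family size."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def hedges_g(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> dict[str, float]:
    """Bias-corrected standardized mean difference with a 95% CI.

    Cohen's d on the (n-1)-weighted pooled SD, corrected by
    J = 1 - 3/(4(n1+n2)-9); the CI uses the conventional large-sample
    variance (n1+n2)/(n1 n2) + g^2 / (2(n1+n2-2)).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = (mean1 - mean2) / pooled
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = d * j
    se = math.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2 - 2)))
    return {
        "g": g,
        "ci_low": g - 1.96 * se,
        "ci_high": g + 1.96 * se,
        "band": interpret_es(g),
    }


def interpret_es(g: float) -> str:
    """Magnitude band for |g|: none <0.20, small <0.50, medium <0.80, large >=0.80."""
    if not math.isfinite(g):
        raise ValueError("g must be finite")
    a = abs(g)
    if a < 0.20:
        return "none"
    if a < 0.50:
        return "small"
    if a < 0.80:
        return "medium"
    return "large"


def posthoc_table(panel: OutcomePanel) -> pd.DataFrame:
    """All pairwise group contrasts within timepoint (independent t) plus all
    pairwise timepoint contrasts within group (paired t), Bonferroni-adjusted
    with m = family size; each contrast carries its Hedge's g.
    """
    df = panel.data
    rows = []
    for tp in panel.timepoints:
        sub = df[df["timepoint"] == tp]
        for g1, g2 in combinations(panel.groups, 2):
            a = sub.loc[sub["group"] == g1, "value"].to_numpy()
            b = sub.loc[sub["group"] == g2, "value"].to_numpy()
            t, p = sps.ttest_ind(a, b)
            es = hedges_g(a.mean(), a.std(ddof=1), len(a),
                          b.mean(), b.std(ddof=1), len(b))
            rows.append({
                "contrast": f"{g1} vs {g2} @ {tp}", "kind": "between",
                "mean_diff": a.mean() - b.mean(), "p_raw": float(p),
                "hedges_g": es["g"], "g_ci_low": es["ci_low"],
                "g_ci_high": es["ci_high"], "band": es["band"],
            })
    for g in panel.groups:
        sub = df[df["group"] == g].pivot(
            index="subject_id", columns="timepoint", values="value"
        )
        for t1, t2 in combinations(panel.timepoints, 2):
            a, b = sub[t1].to_numpy(), sub[t2].to_numpy()
            t, p = sps.ttest_rel(a, b)
            es = hedges_g(a.mean(), a.std(ddof=1), len(a),
                          b.mean(), b.std(ddof=1), len(b))
            rows.append({
                "contrast": f"{g}: {t1} vs {t2}", "kind": "within",
                "mean_diff": a.mean() - b.mean(), "p_raw": float(p),
                "hedges_g": es["g"], "g_ci_low": es["ci_low"],
                "g_ci_high": es["ci_high"], "band": es["band"],
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p_raw"].to_numpy())
    return out


def ancova_adjust(
    panel: OutcomePanel,
    covariates: pd.DataFrame,
) -> dict:
    """Covariate-adjusted group x time means via a linear model.

    ``covariates`` has one row per subject_id with numeric covariate columns
    (e.g. daily kcal intake and steps/day).  The model regresses value on
    group, timepoint, their interaction and the centred covariates; adjusted
    cell means are model predictions at the covariate grand means, so
    zero-slope covariates leave the raw means untouched.
    """
    import statsmodels.formula.api as smf

    cov_cols = [c for c in covariates.columns if c != "subject_id"]
    if not cov_cols:
        raise ValueError("at least one covariate column is required")
    df = panel.data.merge(covariates, on="subject_id", how="inner", validate="m:1")
    if df.empty:
        raise ValueError("no overlap between panel subjects and covariates")

    X = df[cov_cols].to_numpy(dtype=float)
    collinear = False
    if len(cov_cols) > 1:
        corr = np.corrcoef(X, rowvar=False)
        off = corr[~np.eye(len(cov_cols), dtype=bool)]
        collinear = bool(np.any(np.abs(off) > 0.999))
    for c in cov_cols:
        df[f"_c_{c}"] = df[c] - df[c].mean()

    terms = " + ".join(f"_c_{c}" for c in cov_cols)
    model = smf.ols(
        f"value ~ C(group) * C(timepoint) + {terms}", data=df
    ).fit()
    grid = df[["group", "timepoint"]].drop_duplicates().copy()
    for c in cov_cols:
        grid[f"_c_{c}"] = 0.0
    grid["adjusted_mean"] = model.predict(grid)
    adjusted = grid.pivot(index="group", columns="timepoint", values="adjusted_mean")
    adjusted = adjusted[panel.timepoints]

    from statsmodels.stats.anova import anova_lm

    aov = anova_lm(model, typ=2)
    return {
        "adjusted_means": adjusted,
        "raw_means": panel.cell_means()[panel.timepoints],
        "anova": aov,
        "group_p": float(aov.loc["C(group)", "PR(>F)"]),
        "interaction_p": float(aov.loc["C(group):C(timepoint)", "PR(>F)"]),
        "covariate_slopes": {c: float(model.params[f"_c_{c}"]) for c in cov_cols},
        "collinear_covariates": collinear,
    }


def percent_change(pre: float, post: float) -> float:
    """Relative change from pre to post, in percent."""
    if pre == 0:
        raise ValueError("pre value must be nonzero")
    return (post - pre) / pre * 100.0
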