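"""Diet-recall processing.

Summarizes 7-day diet recalls into daily energy intake and macronutrient
energy shares (Atwater 4/4/9 kcal per gram), derives the isocaloric intake
target from resting metabolic rate, and checks a summary against the
prescription bands (55-60% carbohydrate, 15-20% protein, 20-25% fat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from pydantic import BaseModel, Field, model_validator

from .config import IntakeConstants

__all__ = [
    "DietRecallDay",
    "PrescriptionBands",
    "IntakeSummary",
    "mean_energy_intake",
    "isocaloric_target",
    "prescription_check",
]


class DietRecallDay(BaseModel):
    """One day of a diet recall, macronutrient grams and optional energy."""

    date: object = None
    protein_g: float = Field(ge=0)
    carbohydrate_g: float = Field(ge=0)
    fat_g: float = Field(ge=0)
    energy_kcal: float | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_energy(self) -> "DietRecallDay":
        if self.energy_kcal is not None:
            expected = self.computed_kcal()
            if expected > 0 and abs(self.energy_kcal - expected) > 0.05 * expected:
                warnings.warn(
                    f"recorded energy {self.energy_kcal:.0f} kcal differs from "
                    f"4P+4C+9F = {expected:.0f} kcal by more than 5%",
                    stacklevel=2,
                )
        return self

    def computed_kcal(
        self, p: float = 4.0, c: float = 4.0, f: float = 9.0
    ) -> float:
        return p * self.protein_g + c * self.carbohydrate_g + f * self.fat_g


class PrescriptionBands(BaseModel):
    """Macro-share bands and the energy target of the isocaloric prescription."""

    cho_pct: tuple[float, float] = (55.0, 60.0)
    pro_pct: tuple[float, float] = (15.0, 20.0)
    fat_pct: tuple[float, float] = (20.0, 25.0)
    target_kcal: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check_bands(self) -> "PrescriptionBands":
        for name in ("cho_pct", "pro_pct", "fat_pct"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 100):
                raise ValueError(f"{name} band must satisfy 0 <= low <= high <= 100")
        return self


@dataclass
class IntakeSummary:
    """Mean daily energy and period macronutrient energy shares."""

    energy_kcal_day: float
    protein_pct: float
    cho_pct: float
    fat_pct: float
    n_days: int


def mean_energy_intake(
    recalls: Sequence[DietRecallDay],
    constants: IntakeConstants | None = None,
) -> IntakeSummary:
    """Mean daily energy intake and macro shares over a recall period.

    Daily energy is recomputed from grams (Atwater factors); macronutrient
    percentages are computed from grams summed over the whole period, not as
    a mean of daily percentages, so high- and low-intake days weigh in
    proportion to their energy.
    """
    if not recalls:
        raise ValueError("at least one recall day is required")
    c = constants or IntakeConstants()
    p, cg, f = c.kcal_per_g_protein, c.kcal_per_g_carbohydrate, c.kcal_per_g_fat
    daily = [d.computed_kcal(p, cg, f) for d in recalls]
    protein_kcal = sum(d.protein_g for d in recalls) * p
    cho_kcal = sum(d.carbohydrate_g for d in recalls) * cg
    fat_kcal = sum(d.fat_g for d in recalls) * f
    total = protein_kcal + cho_kcal + fat_kcal
    if total > 0:
        shares = (protein_kcal / total, cho_kcal / total, fat_kcal / total)
    else:
        shares = (0.0, 0.0, 0.0)
    return IntakeSummary(
        energy_kcal_day=sum(daily) / len(daily),
        protein_pct=shares[0] * 100,
        cho_pct=shares[1] * 100,
        fat_pct=shares[2] * 100,
        n_days=len(recalls),
    )


def isocaloric_target(rmr_kcal_day: float, activity_factor: float = 1.3) -> float:
    """Weight-maintenance energy target: RMR scaled by an activity factor.

    The factor (default 1.3, sedentary-to-light) approximates habitual
    physical activity on top of resting metabolism; it is re-derivable
    mid-intervention when RMR is re-measured.
    """
    if rmr_kcal_day <= 0:
        raise ValueError("RMR must be positive")
    if activity_factor <= 0:
        raise ValueError("activity factor must be positive")
    return rmr_kcal_day * activity_factor


def prescription_check(
    summary: IntakeSummary,
    bands: PrescriptionBands | None = None,
    kcal_tolerance_pct: float = 5.0,
) -> dict[str, bool]:
    """Check an intake summary against the prescription.

    Returns per-criterion pass flags for each macro band, the energy target
    (when the bands carry one) and overall compliance.  Macro percentages
    must sum to ~100 (+-2) before banding; a summary violating that is
    rejected outright.
    """
    b = bands or PrescriptionBands()
    if summary.energy_kcal_day == 0:
        report = {"cho_in_band": False, "pro_in_band": False, "fat_in_band": False}
        if b.target_kcal is not None:
            report["energy_on_target"] = False
        report["all_pass"] = False
        return report
    total_pct = summary.protein_pct + summary.cho_pct + summary.fat_pct
    if abs(total_pct - 100.0) > 2.0:
        raise ValueError(
            f"macro percentages sum to {total_pct:.1f}; must be 100 +- 2 "
            "before band checking"
        )
    report = {
        "cho_in_band": b.cho_pct[0] <= summary.cho_pct <= b.cho_pct[1],
        "pro_in_band": b.pro_pct[0] <= summary.protein_pct <= b.pro_pct[1],
        "fat_in_band": b.fat_pct[0] <= summary.fat_pct <= b.fat_pct[1],
    }
    if b.target_kcal is not None:
        tol = kcal_tolerance_pct / 100.0 * b.target_kcal
        report["energy_on_target"] = (
            abs(summary.energy_kcal_day - b.target_kcal) <= tol
        )
    report["all_pass"] = all(report.values())
    return report
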