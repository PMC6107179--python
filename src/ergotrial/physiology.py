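"""Bespoke physiological arithmetic.

Resting metabolic rate from resting gas exchange (Weir equation), the
three-component decomposition of an exercise session's energy cost
(aerobic + lactate-anaerobic + EPOC), MET and MET-hour training load,
heart-rate intensity expressions, and simple anthropometric indices.

All energy figures are kilocalories.  Oxygen volumes are litres unless a
field name says otherwise (``mean_vo2`` on a session is the conventional
mass-specific mL·kg^-1·min^-1).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .config import EnergyConstants

__all__ = [
    "GasExchange",
    "SessionPhysiology",
    "PhaseProtocol",
    "Anthropometry",
    "weir_rmr",
    "aerobic_ee",
    "anaerobic_ee",
    "epoc_kcal",
    "session_tee",
    "mets_from_vo2",
    "met_hours",
    "weekly_met_hours",
    "intensity_summary",
    "bmi",
    "whr",
    "PHASE_PROTOCOLS",
]

_MIN_PER_DAY = 1440.0


class GasExchange(BaseModel):
    """Steady-state gas exchange, litres per minute."""

    vo2: float = Field(ge=0, description="oxygen uptake (L·min⁻¹)")
    vco2: float = Field(ge=0, description="carbon-dioxide output (L·min⁻¹)")

    @model_validator(mode="after")
    def _warn_rer(self) -> "GasExchange":
        if self.vo2 > 0:
            rer = self.vco2 / self.vo2
            if not 0.6 < rer < 1.3:
                warnings.warn(
                    f"respiratory exchange ratio {rer:.2f} outside the "
                    "physiological range (0.6, 1.3)",
                    stacklevel=2,
                )
        return self

    @property
    def rer(self) -> float:
        if self.vo2 <= 0:
            raise ValueError("RER undefined when vo2 is 0")
        return self.vco2 / self.vo2


class SessionPhysiology(BaseModel):
    """One monitored exercise session's physiological record."""

    phase: int = Field(ge=1, le=4)
    mean_hr: float = Field(gt=0)
    max_hr: float = Field(gt=0)
    lactate_pre: float = Field(gt=0)
    lactate_mid: float = Field(gt=0)
    lactate_post: float = Field(gt=0)
    mean_vo2: float = Field(ge=0, description="mL·kg⁻¹·min⁻¹")
    ve: float | None = Field(default=None, ge=0)
    rer: float | None = None
    rpe: float = Field(ge=6, le=20)
    #: minute-sampled post-exercise VO2-above-rest trace (L·min⁻¹), if recorded
    epoc_trace: list[float] | None = None
    #: pre-integrated EPOC volume (L), if the trace was not kept
    epoc_litres: float | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SessionPhysiology":
        if self.mean_hr > self.max_hr:
            raise ValueError("mean_hr cannot exceed max_hr")
        if self.epoc_trace is not None and any(v < 0 for v in self.epoc_trace):
            raise ValueError("EPOC trace values must be nonnegative")
        return self


class PhaseProtocol(BaseModel):
    """Timed circuit structure of one training phase."""

    phase: int = Field(ge=1, le=4)
    session_duration_min: float = Field(gt=0)
    effort_time_min: float = Field(gt=0)
    work_interval_s: float = Field(gt=0)
    rest_interval_s: float = Field(gt=0)
    n_exercises: int = Field(gt=0)
    n_rounds: int = Field(gt=0)
    rest_per_round_min: float = Field(ge=0)
    sessions_per_week: int = 3
    metabolic_duration_min: float = Field(gt=0)

    @property
    def recovery_time_min(self) -> float:
        # effort time = session duration - recovery time
        return self.session_duration_min - self.effort_time_min

    @property
    def work_rest_ratio(self) -> float:
        return self.work_interval_s / self.rest_interval_s


#: The four training phases of the circuit protocol.  The metabolic duration is
#: the span over which METs and kcal/min are expressed (distinct from the full
#: session duration, which includes within-circuit recovery).
PHASE_PROTOCOLS: dict[int, PhaseProtocol] = {
    1: PhaseProtocol(phase=1, session_duration_min=23.0, effort_time_min=6.66,
                     work_interval_s=20, rest_interval_s=40, n_exercises=10,
                     n_rounds=2, rest_per_round_min=3.0, metabolic_duration_min=18.0),
    2: PhaseProtocol(phase=2, session_duration_min=38.0, effort_time_min=16.5,
                     work_interval_s=30, rest_interval_s=30, n_exercises=11,
                     n_rounds=3, rest_per_round_min=2.5, metabolic_duration_min=30.0),
    3: PhaseProtocol(phase=3, session_duration_min=41.0, effort_time_min=24.0,
                     work_interval_s=40, rest_interval_s=20, n_exercises=12,
                     n_rounds=3, rest_per_round_min=2.5, metabolic_duration_min=36.0),
    4: PhaseProtocol(phase=4, session_duration_min=41.0, effort_time_min=24.0,
                     work_interval_s=40, rest_interval_s=20, n_exercises=12,
                     n_rounds=3, rest_per_round_min=2.0, metabolic_duration_min=36.0),
}


class Anthropometry(BaseModel):
    """One participant's body measurements."""

    mass_kg: float = Field(gt=0)
    height_m: float = Field(gt=0)
    waist_cm: float = Field(gt=0)
    hip_cm: float = Field(gt=0)
    body_fat_pct: float | None = Field(default=None, ge=0, le=100)
    fat_mass_kg: float | None = Field(default=None, ge=0)
    ffm_kg: float | None = Field(default=None, ge=0)
    resting_hr: float | None = Field(default=None, gt=0)
    max_hr_test: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _warn_consistency(self) -> "Anthropometry":
        if not 1.2 < self.height_m < 2.2:
            warnings.warn(
                f"height {self.height_m:.2f} m outside plausible range", stacklevel=2
            )
        if self.fat_mass_kg is not None and self.ffm_kg is not None:
            total = self.fat_mass_kg + self.ffm_kg
            if abs(total - self.mass_kg) > 0.05 * self.mass_kg:
                warnings.warn(
                    "fat mass + fat-free mass differs from body mass by more "
                    f"than 5% ({total:.1f} vs {self.mass_kg:.1f} kg)",
                    stacklevel=2,
                )
        return self


def weir_rmr(gas: GasExchange, *, weir_a: float = 3.941, weir_b: float = 1.106) -> float:
    """24-hour resting metabolic rate (kcal·day⁻¹) from resting gas exchange.

    Weir's abbreviated equation: kcal/min = a·VO2 + b·VCO2 with VO2/VCO2 in
    L·min⁻¹, scaled to a day.
    """
    return (weir_a * gas.vo2 + weir_b * gas.vco2) * _MIN_PER_DAY


def aerobic_ee(
    mean_vo2: float,
    mass_kg: float,
    duration_min: float,
    kcal_per_litre: float = 5.05,
) -> float:
    """Aerobic energy expenditure of a session (kcal).

    ``mean_vo2`` is the session-mean oxygen uptake in mL·kg⁻¹·min⁻¹; the
    oxygen volume is converted at a fixed caloric equivalent (default
    5.05 kcal, i.e. 21.14 kJ, per litre O2).
    """
    if min(mean_vo2, mass_kg, duration_min, kcal_per_litre) < 0:
        raise ValueError("aerobic_ee inputs must be nonnegative")
    litres = mean_vo2 * mass_kg * duration_min / 1000.0
    return litres * kcal_per_litre


def anaerobic_ee(
    lactate_pre: float,
    lactate_post: float,
    mass_kg: float,
    o2_equiv: float = 3.0,
    kcal_per_litre: float = 5.05,
) -> float:
    """Lactate-based anaerobic energy expenditure (kcal).

    Net lactate accumulation (mM) is converted to an oxygen equivalent at
    ``o2_equiv`` mL·kg⁻¹·mM⁻¹ and then to kilocalories.  Accumulation below
    baseline clips to zero (recovery sessions can end below resting lactate).
    """
    if lactate_pre <= 0 or lactate_post <= 0:
        raise ValueError("lactate concentrations must be positive")
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    delta = max(0.0, lactate_post - lactate_pre)
    litres = delta * o2_equiv * mass_kg / 1000.0
    return litres * kcal_per_litre


def epoc_kcal(
    epoc: Sequence[float] | float | None,
    kcal_per_litre: float = 5.05,
) -> float:
    """Excess post-exercise oxygen consumption converted to kcal.

    Accepts either a minute-sampled VO2-above-rest trace (L·min⁻¹) or a
    pre-integrated oxygen volume in litres.  Trace samples are 1-minute
    averages, so the integral is their sum (the trapezoid rule applied to
    the cumulative-volume bin edges reduces to exactly this).  An empty or
    absent trace yields 0.
    """
    if epoc is None:
        return 0.0
    if np.isscalar(epoc):
        volume = float(epoc)  # pre-integrated litres
        if volume < 0:
            raise ValueError("EPOC volume must be nonnegative")
    else:
        trace = np.asarray(epoc, dtype=float)
        if trace.size == 0:
            return 0.0
        if (trace < 0).any():
            raise ValueError("EPOC trace values must be nonnegative")
        volume = float(trace.sum())
    return volume * kcal_per_litre


def session_tee(aee: float, anee: float, epoc: float) -> float:
    """Total session energy expenditure: aerobic + anaerobic + EPOC (kcal)."""
    if min(aee, anee, epoc) < 0:
        raise ValueError("energy components must be nonnegative")
    return aee + anee + epoc


def mets_from_vo2(mean_vo2: float, met_ml_per_kg_min: float = 3.5) -> float:
    """Session intensity in METs (1 MET = 3.5 mL O2·kg⁻¹·min⁻¹)."""
    if mean_vo2 < 0:
        raise ValueError("mean_vo2 must be nonnegative")
    return mean_vo2 / met_ml_per_kg_min


def met_hours(mets: float, metabolic_duration_min: float) -> float:
    """Per-session training load in MET·hours."""
    if mets < 0 or metabolic_duration_min < 0:
        raise ValueError("inputs must be nonnegative")
    return mets * metabolic_duration_min / 60.0


def weekly_met_hours(met_hours_per_session: float, sessions_per_week: int = 3) -> float:
    """Weekly metabolic dose, MET·hours·week⁻¹."""
    if met_hours_per_session < 0 or sessions_per_week < 0:
        raise ValueError("inputs must be nonnegative")
    return met_hours_per_session * sessions_per_week


def intensity_summary(
    session: SessionPhysiology,
    anth: Anthropometry,
    hrr_target_pct: float = 65.0,
) -> dict[str, float | bool]:
    """Express a session's mean heart rate relative to maximum and reserve.

    Returns ``pct_max_hr``, ``pct_hrr`` and whether the heart-rate-reserve
    target (default 65%) was met.  Requires the participant's resting HR and
    the maximal HR from criterion testing.
    """
    if anth.resting_hr is None or anth.max_hr_test is None:
        raise ValueError("resting_hr and max_hr_test are required")
    if anth.resting_hr >= anth.max_hr_test:
        raise ValueError("resting_hr must be below max_hr_test")
    if not anth.resting_hr <= session.mean_hr <= anth.max_hr_test:
        warnings.warn(
            "session mean HR outside the resting-to-max window", stacklevel=2
        )
    pct_max = session.mean_hr / anth.max_hr_test * 100.0
    pct_hrr = (
        (session.mean_hr - anth.resting_hr)
        / (anth.max_hr_test - anth.resting_hr)
        * 100.0
    )
    return {
        "pct_max_hr": pct_max,
        "pct_hrr": pct_hrr,
        "meets_hrr_target": pct_hrr >= hrr_target_pct,
    }


def bmi(mass_kg: float, height_m: float) -> float:
    """Body-mass index, kg·m⁻²."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return mass_kg / height_m**2


def whr(waist_cm: float, hip_cm: float) -> float:
    """Waist-to-hip circumference ratio."""
    if hip_cm <= 0:
        raise ValueError("hip circumference must be positive")
    return waist_cm / hip_cm


def session_energy(
    session: SessionPhysiology,
    mass_kg: float,
    constants: EnergyConstants | None = None,
) -> dict[str, float]:
    """Full energy decomposition of one session at the configured constants.

    Returns aee/anee/epoc/tee in kcal plus the MET chain (mets, met_hours,
    weekly_met_hours, kcal/min) for the session's phase.
    """
    c = constants or EnergyConstants()
    aee = aerobic_ee(
        session.mean_vo2, mass_kg, c.aee_duration(session.phase), c.kcal_per_litre_o2
    )
    anee = anaerobic_ee(
        session.lactate_pre, session.lactate_post, mass_kg,
        c.lactate_o2_equiv, c.kcal_per_litre_o2,
    )
    epoc = epoc_kcal(
        session.epoc_trace if session.epoc_trace is not None else session.epoc_litres,
        c.kcal_per_litre_o2,
    )
    tee = session_tee(aee, anee, epoc)
    mets = mets_from_vo2(session.mean_vo2, c.met_ml_per_kg_min)
    duration = c.metabolic_duration(session.phase)
    mh = met_hours(mets, duration)
    return {
        "aee_kcal": aee,
        "anee_kcal": anee,
        "epoc_kcal": epoc,
        "tee_kcal": tee,
        "mets": mets,
        "met_hours": mh,
        "weekly_met_hours": weekly_met_hours(mh, c.sessions_per_week),
        "kcal_per_min": tee / duration,
    }
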