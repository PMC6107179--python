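"""Configuration objects shared across the pipeline.

All energy conversion constants, accelerometer processing constants and diet
bookkeeping constants live in one :class:`StudyConfig` object so that every
report can embed the exact constants it was computed with.  Values default to
the conventions used throughout exercise physiology (Weir 1949 coefficients,
5.05 kcal per litre O2, 1 MET = 3.5 mL O2·kg^-1·min^-1, Freedson 1998 count
equations, Choi-style non-wear parameters, Atwater 4/4/9 factors, 7700 kcal
per kg of adipose tissue) and are overridable from YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class EnergyConstants(BaseModel):
    """Constants for resting and exercise energy-expenditure arithmetic."""

    kcal_per_litre_o2: float = 5.05
    kj_per_litre_o2: float = 21.14
    weir_a: float = 3.941  # kcal per L O2
    weir_b: float = 1.106  # kcal per L CO2
    met_ml_per_kg_min: float = 3.5
    lactate_o2_equiv: float = 3.0  # mL O2 · kg^-1 · mM^-1 (di Prampero convention)
    #: duration over which session METs and kcal/min are expressed, per phase
    metabolic_duration_by_phase: dict[int, float] = Field(
        default_factory=lambda: {1: 18.0, 2: 30.0, 3: 36.0, 4: 36.0}
    )
    #: circuit arithmetic alternative (exercises x rounds x interval)
    circuit_duration_by_phase: dict[int, float] = Field(
        default_factory=lambda: {1: 20.0, 2: 33.0, 3: 36.0, 4: 36.0}
    )
    #: full session duration including within-circuit recovery
    session_duration_by_phase: dict[int, float] = Field(
        default_factory=lambda: {1: 23.0, 2: 38.0, 3: 41.0, 4: 41.0}
    )
    #: duration fed to the aerobic-EE integral; "metabolic", "circuit" or "session"
    aee_duration_mode: Literal["metabolic", "circuit", "session"] = "metabolic"
    duration_mode: Literal["metabolic", "circuit"] = "metabolic"
    sessions_per_week: int = 3
    hrr_target_pct: float = 65.0

    def metabolic_duration(self, phase: int) -> float:
        table = (
            self.metabolic_duration_by_phase
            if self.duration_mode == "metabolic"
            else self.circuit_duration_by_phase
        )
        return table[phase]

    def aee_duration(self, phase: int) -> float:
        table = {
            "metabolic": self.metabolic_duration_by_phase,
            "circuit": self.circuit_duration_by_phase,
            "session": self.session_duration_by_phase,
        }[self.aee_duration_mode]
        return table[phase]


class AccelConstants(BaseModel):
    """Cut-points, wear rules and count-to-energy equations (vertical axis)."""

    sedentary_max_cpm: int = 199
    light_max_cpm: int = 2689
    moderate_max_cpm: int = 6166
    vigorous_ref_max_cpm: int = 9642  # reporting band edge only; not a cap
    # Choi-2011-style non-wear parameters on vector magnitude
    nonwear_window_min: int = 90
    spike_tolerance_min: int = 2
    spike_flank_min: int = 30
    # validity rules
    min_valid_days: int = 4
    min_wear_min: int = 600
    # Freedson-style per-epoch equations gated on the vertical axis
    freedson_gate_cpm: float = 1951.0
    kcal_axis_coef: float = 0.00094
    kcal_mass_coef: float = 0.1346
    kcal_intercept: float = -7.37418
    met_axis_coef: float = 0.000795
    met_intercept: float = 1.439008


class IntakeConstants(BaseModel):
    """Diet-recall bookkeeping constants."""

    kcal_per_g_protein: float = 4.0
    kcal_per_g_carbohydrate: float = 4.0
    kcal_per_g_fat: float = 9.0
    energy_consistency_tol_pct: float = 5.0
    activity_factor: float = 1.3  # sedentary-to-light multiplier on RMR
    cho_band: tuple[float, float] = (55.0, 60.0)
    pro_band: tuple[float, float] = (15.0, 20.0)
    fat_band: tuple[float, float] = (20.0, 25.0)


class LedgerConstants(BaseModel):
    """Energy-ledger constants."""

    fat_energy_density_kcal_per_kg: float = 7700.0
    #: thermic effect of food as a fraction of intake; off by default to mirror
    #: a ledger that books only measured components
    tef_fraction: float = 0.0
    exercise_days_per_week: int = 3


class StatsConstants(BaseModel):
    """Statistical-layer switches."""

    alpha: float = 0.05
    #: apply Greenhouse-Geisser correction only when Mauchly p < alpha
    #: ("conditional") or always ("always")
    gg_mode: Literal["conditional", "always"] = "conditional"


class StudyConfig(BaseModel):
    """Bundle of all constants, hashable for provenance."""

    energy: EnergyConstants = Field(default_factory=EnergyConstants)
    accel: AccelConstants = Field(default_factory=AccelConstants)
    intake: IntakeConstants = Field(default_factory=IntakeConstants)
    ledger: LedgerConstants = Field(default_factory=LedgerConstants)
    stats: StatsConstants = Field(default_factory=StatsConstants)

    @model_validator(mode="after")
    def _check_positive(self) -> "StudyConfig":
        if self.energy.kcal_per_litre_o2 <= 0:
            raise ValueError("kcal_per_litre_o2 must be positive")
        if self.ledger.fat_energy_density_kcal_per_kg <= 0:
            raise ValueError("fat energy density must be positive")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.model_dump(mode="json")
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))


DEFAULT_CONFIG = StudyConfig()
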