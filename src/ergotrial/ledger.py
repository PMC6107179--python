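"""Daily, weekly and period energy-balance accounting.

The ledger is an accounting identity, not a physiological model: one day's
balance is intake minus the sum of resting metabolic rate, habitual-activity
kilocalories and (on training days) the exercise session's energy cost.
Cumulative deficits convert to a fat-mass equivalent at a configurable
adipose energy density (default 7700 kcal per kg).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

__all__ = [
    "EnergyLedgerDay",
    "PeriodBalance",
    "day_balance",
    "week_balance",
    "period_total",
    "period_fat_equivalent",
]


@dataclass(frozen=True)
class EnergyLedgerDay:
    """One day's intake-minus-expenditure balance, typed by day kind."""

    intake_kcal: float
    rmr_kcal: float
    activity_kcal: float
    exercise_kcal: float
    balance_kcal: float
    day_type: Literal["exercise", "non-exercise"]
    date: object = None


@dataclass(frozen=True)
class PeriodBalance:
    """Aggregate balance of a multi-week period and its fat equivalent."""

    weeks: float
    weekly_balance_kcal: float
    total_balance_kcal: float
    fat_equivalent_kg: float
    fat_rate_kg_per_week: float


def day_balance(
    intake_kcal: float,
    rmr_kcal: float,
    activity_kcal: float,
    exercise_kcal: float = 0.0,
    tef_fraction: float = 0.0,
    date: object = None,
) -> EnergyLedgerDay:
    """Signed daily energy balance (positive = surplus).

    ``tef_fraction`` optionally books the thermic effect of food as a fixed
    share of intake; it defaults off so the ledger carries only measured
    components.
    """
    if min(intake_kcal, rmr_kcal, activity_kcal, exercise_kcal) < 0:
        raise ValueError("ledger components must be nonnegative")
    if not 0 <= tef_fraction < 1:
        raise ValueError("tef_fraction must be in [0, 1)")
    tef = tef_fraction * intake_kcal
    balance = intake_kcal - (rmr_kcal + activity_kcal + exercise_kcal + tef)
    return EnergyLedgerDay(
        intake_kcal=intake_kcal,
        rmr_kcal=rmr_kcal,
        activity_kcal=activity_kcal,
        exercise_kcal=exercise_kcal,
        balance_kcal=balance,
        day_type="exercise" if exercise_kcal > 0 else "non-exercise",
        date=date,
    )


def week_balance(
    exercise_day: EnergyLedgerDay,
    nonexercise_day: EnergyLedgerDay,
    n_exercise_days: int = 3,
) -> float:
    """Weekly balance from a representative exercise and non-exercise day."""
    if not 0 <= n_exercise_days <= 7:
        raise ValueError("n_exercise_days must be in [0, 7]")
    return (
        n_exercise_days * exercise_day.balance_kcal
        + (7 - n_exercise_days) * nonexercise_day.balance_kcal
    )


def period_total(days: Iterable[EnergyLedgerDay]) -> float:
    """Exact sum of daily balances over a period (ledger conservation)."""
    return sum(d.balance_kcal for d in days)


def period_fat_equivalent(
    total_balance_kcal: float,
    weeks: float,
    energy_density_kcal_per_kg: float = 7700.0,
) -> PeriodBalance:
    """Convert a cumulative balance to fat-mass change and weekly rate.

    Sign is retained: a deficit (negative balance) maps to fat loss
    (negative kg).
    """
    if weeks <= 0:
        raise ValueError("weeks must be positive")
    if energy_density_kcal_per_kg <= 0:
        raise ValueError("energy density must be positive")
    fat_kg = total_balance_kcal / energy_density_kcal_per_kg
    return PeriodBalance(
        weeks=weeks,
        weekly_balance_kcal=total_balance_kcal / weeks,
        total_balance_kcal=total_balance_kcal,
        fat_equivalent_kg=fat_kg,
        fat_rate_kg_per_week=fat_kg / weeks,
    )
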