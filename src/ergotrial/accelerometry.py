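"""Accelerometer count-stream processing.

Turns 60-second epoch count streams (ActiGraph-export-like CSV) into
wear-validated daily activity summaries: Choi-style non-wear detection on
vector-magnitude counts, cut-point intensity classification, steps/day,
activity kilocalories and mean daily METs from Freedson-style vertical-axis
equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AccelConstants

__all__ = [
    "DaySummary",
    "read_epoch_csv",
    "detect_nonwear",
    "classify_intensity",
    "summarize_day",
    "summarize_days",
    "valid_wear_filter",
]

BANDS = ("sedentary", "light", "moderate", "vigorous")

EPOCH_COLUMNS = ["timestamp", "axis1", "axis2", "axis3", "steps"]


@dataclass
class DaySummary:
    """Wear-validated roll-up of one calendar day of 60-s epochs."""

    date: object
    wear_min: int
    steps: int
    sedentary_min: int
    light_min: int
    moderate_min: int
    vigorous_min: int
    activity_kcal: float
    mean_mets: float
    #: True when the day had zero wear minutes and mean_mets is undefined
    mets_undefined: bool = False
    partial: bool = False

    @property
    def mvpa_min(self) -> int:
        return self.moderate_min + self.vigorous_min

    def band_minutes(self) -> dict[str, int]:
        return {
            "sedentary": self.sedentary_min,
            "light": self.light_min,
            "moderate": self.moderate_min,
            "vigorous": self.vigorous_min,
        }


def read_epoch_csv(path) -> pd.DataFrame:
    """Read an ActiGraph-like epoch CSV (one row per 60-s epoch).

    Required columns: timestamp, axis1, axis2, axis3, steps; an optional
    ``vm`` column is recomputed as the Euclidean norm of the axes if absent.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epoch file {path} missing columns {missing}")
    if "vm" not in df.columns:
        df["vm"] = np.sqrt(
            df["axis1"] ** 2 + df["axis2"] ** 2 + df["axis3"] ** 2
        )
    for col in ["axis1", "axis2", "axis3", "vm", "steps"]:
        if (df[col] < 0).any():
            row = int(df.index[df[col] < 0][0])
            raise ValueError(f"negative {col} at row {row} of {path}")
    return df


def _zero_runs(zero: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean array as (start, length, is_zero)."""
    if zero.size == 0:
        return []
    change = np.flatnonzero(np.diff(zero.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [zero.size]))
    return [(int(s), int(e - s), bool(zero[s])) for s, e in zip(starts, ends)]


def detect_nonwear(
    epochs: pd.DataFrame,
    window_min: int = 90,
    spike_tolerance_min: int = 2,
    spike_flank_min: int = 30,
) -> np.ndarray:
    """Label each epoch as worn (True) or not worn (False).

    A block of epochs is non-wear when it is a run of at least ``window_min``
    zero vector-magnitude minutes; runs may absorb interruptions of up to
    ``spike_tolerance_min`` consecutive nonzero minutes provided each
    interruption is flanked by at least ``spike_flank_min`` zero minutes on
    both sides.  Labelling is idempotent and order-deterministic.
    """
    ts = pd.to_datetime(epochs["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("epoch timestamps must be strictly increasing")
    vm = epochs["vm"].to_numpy(dtype=float)
    wear = np.ones(vm.size, dtype=bool)
    runs = _zero_runs(vm == 0)
    if not runs:
        return wear

    # Merge zero runs across tolerated spikes, then flag blocks >= window.
    i = 0
    while i < len(runs):
        start, length, is_zero = runs[i]
        if not is_zero:
            i += 1
            continue
        block_start, block_len = start, length
        j = i
        # absorb [spike, zero-run] pairs while each spike is short enough and
        # flanked by long-enough zero runs on both sides
        while j + 2 < len(runs):
            spike_len = runs[j + 1][1]
            left_len = runs[j][1]
            right_len = runs[j + 2][1]
            if (
                spike_len <= spike_tolerance_min
                and left_len >= spike_flank_min
                and right_len >= spike_flank_min
            ):
                block_len += spike_len + right_len
                j += 2
            else:
                break
        if block_len >= window_min:
            wear[block_start : block_start + block_len] = False
        i = j + 1
    return wear


def classify_intensity(
    vm: float | np.ndarray, constants: AccelConstants | None = None
) -> np.ndarray | str:
    """Map vector-magnitude counts·min⁻¹ to an intensity band.

    Bands (counts per minute): sedentary <=199, light 200-2689,
    moderate 2690-6166, vigorous >=6167 (open above; the conventional 9642
    upper edge is a reporting band edge, not a cap).
    """
    c = constants or AccelConstants()
    arr = np.asarray(vm)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    edges = [c.sedentary_max_cpm, c.light_max_cpm, c.moderate_max_cpm]
    idx = np.digitize(arr, [e + 0.5 for e in edges])
    bands = np.array(BANDS, dtype=object)[idx]
    if arr.ndim == 0:
        return str(bands)
    return bands


def _epoch_kcal(axis1: np.ndarray, mass_kg: float, c: AccelConstants) -> np.ndarray:
    """Per-epoch activity kcal: Freedson-style, gated on the vertical axis."""
    kcal = c.kcal_axis_coef * axis1 + c.kcal_mass_coef * mass_kg + c.kcal_intercept
    kcal = np.clip(kcal, 0.0, None)
    return np.where(axis1 > c.freedson_gate_cpm, kcal, 0.0)


def _epoch_mets(axis1: np.ndarray, c: AccelConstants) -> np.ndarray:
    mets = c.met_axis_coef * axis1 + c.met_intercept
    return np.where(axis1 > c.freedson_gate_cpm, mets, 1.0)


def summarize_day(
    epochs: pd.DataFrame,
    mass_kg: float,
    wear: np.ndarray | None = None,
    constants: AccelConstants | None = None,
    partial: bool = False,
) -> DaySummary:
    """Roll one calendar day of labelled epochs up into a :class:`DaySummary`.

    Steps and band minutes count wear epochs only; band minutes partition
    wear time exactly.  Activity kcal and per-epoch METs use the gated
    vertical-axis equations in the constants object.
    """
    c = constants or AccelConstants()
    if wear is None:
        wear = detect_nonwear(
            epochs, c.nonwear_window_min, c.spike_tolerance_min, c.spike_flank_min
        )
    wear = np.asarray(wear, dtype=bool)
    date = pd.to_datetime(epochs["timestamp"].iloc[0]).date()
    worn = epochs.loc[wear]
    wear_min = int(wear.sum())
    if wear_min == 0:
        return DaySummary(
            date=date, wear_min=0, steps=0, sedentary_min=0, light_min=0,
            moderate_min=0, vigorous_min=0, activity_kcal=0.0, mean_mets=float("nan"),
            mets_undefined=True, partial=partial,
        )
    vm = worn["vm"].to_numpy(dtype=float)
    bands = classify_intensity(vm, c)
    counts = {b: int((bands == b).sum()) for b in BANDS}
    axis1 = worn["axis1"].to_numpy(dtype=float)
    kcal = float(_epoch_kcal(axis1, mass_kg, c).sum())
    mets = float(_epoch_mets(axis1, c).mean())
    return DaySummary(
        date=date,
        wear_min=wear_min,
        steps=int(worn["steps"].sum()),
        sedentary_min=counts["sedentary"],
        light_min=counts["light"],
        moderate_min=counts["moderate"],
        vigorous_min=counts["vigorous"],
        activity_kcal=kcal,
        mean_mets=mets,
        partial=partial,
    )


def summarize_days(
    epochs: pd.DataFrame,
    mass_kg: float,
    constants: AccelConstants | None = None,
    mark_boundary_partial: bool = True,
) -> list[DaySummary]:
    """Split a multi-day stream into calendar days and summarize each.

    Non-wear detection runs on the full stream first so that blocks spanning
    midnight are handled.  First and last calendar days are marked partial
    when they do not cover a full 1440 minutes.
    """
    c = constants or AccelConstants()
    wear = detect_nonwear(
        epochs, c.nonwear_window_min, c.spike_tolerance_min, c.spike_flank_min
    )
    dates = pd.to_datetime(epochs["timestamp"]).dt.date
    out: list[DaySummary] = []
    unique = list(dict.fromkeys(dates))
    for d in unique:
        mask = (dates == d).to_numpy()
        partial = mark_boundary_partial and d in (unique[0], unique[-1]) and mask.sum() < 1440
        out.append(
            summarize_day(epochs.loc[mask], mass_kg, wear[mask], c, partial=partial)
        )
    return out


def valid_wear_filter(
    days: list[DaySummary],
    min_days: int = 4,
    min_wear_min: int = 600,
) -> tuple[list[DaySummary], bool]:
    """Apply the wear-validity rule: keep days with >= ``min_wear_min`` wear
    minutes; the subject is valid iff at least ``min_days`` days remain.

    Boundary (partial first/last) days never count toward validity.
    Both thresholds are inclusive.
    """
    if not days:
        raise ValueError("at least one day summary is required")
    retained = [d for d in days if d.wear_min >= min_wear_min and not d.partial]
    return retained, len(retained) >= min_days
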