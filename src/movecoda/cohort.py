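"""Participant-level phenotype derivation and the exclusion cascade.

A cohort is a pandas DataFrame with one row per participant.  Column
dictionary (wave suffixes ``_w1`` = age ~4.5 y baseline, ``_w2`` =
age ~9.6 y follow-up):

==================  =========================================================
column              meaning
==================  =========================================================
id                  participant identifier
sex                 0 = boy, 1 = girl
age_w1, age_w2      decimal age in years at each wave
maternal_edu        1 = university level, 0 = below
group               1 = intervention arm, 0 = control
vpa_w*, mpa_w*,     daily time-use composition, minutes/day (5 parts/wave)
lpa_w*, sb_w*,
sleep_w*
height_cm_w*,       anthropometrics
weight_kg_w*
fmi_w*, ffmi_w*     fat mass / fat-free mass index, kg/m^2
aerobic_w*          20-m shuttle-run laps
motor_w*            4x10-m shuttle time, seconds (lower is better)
grip_kg_w*          handgrip strength, kg
longjump_cm_w*      standing long jump, cm
energy_kcal_w*      optional energy intake covariate
accel_valid_w*      accelerometer validity verdict (bool)
bodycomp_complete   complete body-composition data at both waves (bool)
fitness_complete    complete physical-fitness data at both waves (bool)
==================  =========================================================

Derived quantities: relative grip (grip / body weight), the muscular
composite (mean of within-sample z-scores of relative grip and long
jump), BMI and weight status against a caller-supplied age/sex
reference table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionReport",
    "apply_exclusions",
    "derive_bmi",
    "classify_weight_status",
    "derive_relative_grip",
    "derive_muscular_composite",
    "validate_cohort",
]

COMPOSITION_COLS = {
    "w1": ["vpa_w1", "mpa_w1", "lpa_w1", "sb_w1", "sleep_w1"],
    "w2": ["vpa_w2", "mpa_w2", "lpa_w2", "sb_w2", "sleep_w2"],
}

#: Exclusion cascade in the order applied to the follow-up roster.
EXCLUSION_STEPS = (
    ("insufficient_accelerometer", lambda df: ~(df["accel_valid_w1"] & df["accel_valid_w2"])),
    ("incomplete_body_composition", lambda df: ~df["bodycomp_complete"]),
    ("incomplete_physical_fitness", lambda df: ~df["fitness_complete"]),
)


@dataclass(frozen=True)
class ExclusionReport:
    """Counts at each step of the exclusion cascade."""

    initial_n: int
    removed: dict[str, int]
    final_n: int

    def to_dict(self) -> dict:
        return {
            "initial_n": self.initial_n,
            "removed": dict(self.removed),
            "final_n": self.final_n,
        }

    def __str__(self) -> str:  # human-readable log
        lines = [f"roster: {self.initial_n}"]
        n = self.initial_n
        for step, k in self.removed.items():
            n -= k
            lines.append(f"  - {step}: removed {k} -> {n}")
        lines.append(f"analytical sample: {self.final_n}")
        return "\n".join(lines)


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Sequentially remove participants failing each completeness check.

    Each participant is removed at the first step that triggers, so the
    per-step counts partition the excluded set even when flags overlap.
    """
    remaining = df
    removed: dict[str, int] = {}
    for name, trigger in EXCLUSION_STEPS:
        drop = trigger(remaining)
        removed[name] = int(drop.sum())
        remaining = remaining.loc[~drop]
    report = ExclusionReport(initial_n=len(df), removed=removed, final_n=len(remaining))
    return remaining.copy(), report


def derive_bmi(weight_kg, height_cm) -> np.ndarray:
    """BMI = weight / height^2 in kg/m^2."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_cm, dtype=float) / 100.0
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be positive")
    return w / h**2


def classify_weight_status(
    bmi: float, age: float, sex: int, reference: pd.DataFrame
) -> str:
    """Weight status from an age/sex BMI reference table.

    ``reference`` has columns ``sex, age, bmi_underweight, bmi_overweight,
    bmi_obesity``; the row with matching sex and the closest age is used.
    Categories: underweight < bmi_underweight <= normal < bmi_overweight
    <= overweight < bmi_obesity <= obesity.
    """
    rows = reference[reference["sex"] == sex]
    if rows.empty:
        raise ValueError(f"no reference rows for sex={sex}")
    row = rows.iloc[(rows["age"] - age).abs().argmin()]
    if bmi < row["bmi_underweight"]:
        return "underweight"
    if bmi < row["bmi_overweight"]:
        return "normal"
    if bmi < row["bmi_obesity"]:
        return "overweight"
    return "obesity"


def derive_relative_grip(grip_kg, weight_kg) -> np.ndarray:
    """Handgrip strength normalised to body weight (kg squeezed / kg body)."""
    g = np.asarray(grip_kg, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(w <= 0):
        raise ValueError("body weight must be positive")
    return g / w


def derive_muscular_composite(relative_grip, longjump) -> np.ndarray:
    """Muscular-fitness composite: mean of the two within-sample z-scores.

    Both inputs are relative-to-body-weight strength indicators; the
    composite has sample mean 0 by construction and is invariant to
    affine rescaling of either raw input.
    """
    g = np.asarray(relative_grip, dtype=float)
    j = np.asarray(longjump, dtype=float)
    if g.shape != j.shape:
        raise ValueError("inputs must be aligned per participant")
    zg = (g - g.mean()) / g.std(ddof=1)
    zj = (j - j.mean()) / j.std(ddof=1)
    return (zg + zj) / 2.0


def validate_cohort(df: pd.DataFrame) -> None:
    """Check the record invariants; raise ValueError on violation."""
    required = {"id", "sex", "age_w1", "age_w2", "maternal_edu", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    both = df["age_w1"].notna() & df["age_w2"].notna()
    if not (df.loc[both, "age_w2"] > df.loc[both, "age_w1"]).all():
        raise ValueError("follow-up age must exceed baseline age")
    for col in ("height_cm_w1", "height_cm_w2", "weight_kg_w1", "weight_kg_w2"):
        if col in df.columns and (df[col].dropna() <= 0).any():
            raise ValueError(f"{col} must be positive where present")
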