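"""Epoch-level intensity classification and wear-time validity filtering.

Input is an acceleration-magnitude series (ENMO-style, milli-g) at a
fixed epoch length (default 5 s) with per-epoch wear and sleep flags
supplied upstream.  Awake wear epochs are classified by intensity band
(SB < 35 mg, LPA 35–199 mg, MPA 200–699 mg, VPA >= 700 mg, implemented
as half-open real intervals), aggregated to minutes per calendar day,
filtered by the 16-h wear rule, and averaged into one 5-part composition
per person.  Non-wear and sleep detection themselves are out of scope:
the flags arrive in the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coda import DAY_MINUTES, PARTS, closure, replace_zeros

__all__ = [
    "BEHAVIOURS",
    "CutpointConfig",
    "EpochSeries",
    "DailyComposition",
    "classify_epochs",
    "daily_minutes",
    "filter_valid_days",
    "person_composition",
]

#: Label order used throughout; matches the compositional part order.
BEHAVIOURS = PARTS  # ("vigorous", "moderate", "light", "sedentary", "sleep")


@dataclass(frozen=True)
class CutpointConfig:
    """Intensity band edges in milli-g (lower-inclusive, upper-exclusive)."""

    sb_upper: float = 35.0
    lpa_upper: float = 200.0
    mpa_upper: float = 700.0

    def __post_init__(self) -> None:
        if not (0 < self.sb_upper < self.lpa_upper < self.mpa_upper):
            raise ValueError("cut-points must satisfy 0 < sb < lpa < mpa")


@dataclass
class EpochSeries:
    """A person's epoch-level record.

    magnitude : ENMO-style acceleration magnitude per epoch, milli-g, >= 0
    wear      : boolean per-epoch wear flag
    sleep     : boolean per-epoch sleep flag
    day       : integer calendar-day index per epoch
    epoch_len : epoch length in seconds; must divide 60
    """

    magnitude: np.ndarray
    wear: np.ndarray
    sleep: np.ndarray
    day: np.ndarray
    epoch_len: float = 5.0

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        self.sleep = np.asarray(self.sleep, dtype=bool)
        self.day = np.asarray(self.day, dtype=int)
        n = self.magnitude.shape[0]
        if not (self.wear.shape[0] == self.sleep.shape[0] == self.day.shape[0] == n):
            raise ValueError("all per-epoch arrays must have equal length")
        if 60 % self.epoch_len != 0:
            raise ValueError("epoch length must divide 60 seconds")
        if np.any(self.magnitude < 0):
            raise ValueError("acceleration magnitudes must be non-negative")


@dataclass(frozen=True)
class DailyComposition:
    """Minutes per behaviour for one calendar day, plus wear coverage."""

    day: int
    minutes: dict[str, float]
    wear_hours: float


def classify_epochs(series: EpochSeries, cut: CutpointConfig | None = None) -> np.ndarray:
    """Label each epoch with its behaviour.

    Sleep-flagged epochs are labelled ``sleep`` regardless of magnitude;
    awake epochs fall into the intensity band containing their magnitude.
    Returns an object array of labels (one per epoch, including non-wear
    epochs, which are labelled but excluded downstream).
    """
    cut = cut or CutpointConfig()
    m = series.magnitude
    awake_label = np.select(
        [m < cut.sb_upper, m < cut.lpa_upper, m < cut.mpa_upper],
        ["sedentary", "light", "moderate"],
        default="vigorous",
    )
    return np.where(series.sleep, "sleep", awake_label)


def daily_minutes(
    series: EpochSeries, cut: CutpointConfig | None = None
) -> list[DailyComposition]:
    """Aggregate classified wear epochs to minutes/day per behaviour.

    Non-wear epochs contribute to neither behaviour minutes nor wear
    hours; no imputation is applied (the compositional closure performed
    later normalises relative time use).
    """
    labels = classify_epochs(series, cut)
    per_min = series.epoch_len / 60.0
    out = []
    for d in np.unique(series.day):
        sel = (series.day == d) & series.wear
        day_labels = labels[sel]
        minutes = {b: float((day_labels == b).sum() * per_min) for b in BEHAVIOURS}
        out.append(
            DailyComposition(day=int(d), minutes=minutes, wear_hours=sel.sum() * per_min / 60.0)
        )
    return out


def filter_valid_days(
    days: list[DailyComposition],
    min_wear_hours: float = 16.0,
    min_days: int = 1,
) -> tuple[list[DailyComposition], bool]:
    """Apply the wear-time validity rule.

    A day is valid if it has at least ``min_wear_hours`` of wear; the
    participant is valid if at least ``min_days`` days survive.  The
    default (16 h, 1 day) is the primary inclusion rule; ``min_days=3``
    reproduces the stricter sensitivity-analysis rule.
    """
    valid = [d for d in days if d.wear_hours >= min_wear_hours]
    return valid, len(valid) >= min_days


def person_composition(valid_days: list[DailyComposition]) -> np.ndarray:
    """Average behaviour minutes over valid days, then close to 1440.

    Zero behaviours (possible for VPA) are floored at 1 min/day by
    multiplicative replacement before closure.
    """
    if not valid_days:
        raise ValueError("no valid days to average")
    mat = np.array([[d.minutes[b] for b in BEHAVIOURS] for d in valid_days])
    mean = mat.mean(axis=0)
    if np.any(mean <= 0):
        mean = replace_zeros(mean)
    return closure(mean, DAY_MINUTES)


def epochs_from_frame(df: pd.DataFrame, epoch_len: float = 5.0) -> EpochSeries:
    """Build an :class:`EpochSeries` from a long-format table with columns
    ``day, magnitude, wear, sleep`` (the delimited-text epoch interface)."""
    return EpochSeries(
        magnitude=df["magnitude"].to_numpy(),
        wear=df["wear"].to_numpy(),
        sleep=df["sleep"].to_numpy(),
        day=df["day"].to_numpy(),
        epoch_len=epoch_len,
    )
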