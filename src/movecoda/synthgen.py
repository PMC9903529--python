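"""Seeded synthetic-cohort generator.

Emulates the structure of a two-wave preschool-to-childhood cohort in
which daily movement behaviours (ILR coordinates of the 5-part time-use
composition), body composition (FMI, FFMI) and physical fitness
(aerobic, motor, muscular) are measured at ~4.5 and ~9.6 years of age.

The data-generating process is logistic-normal: wave-1 ILR coordinates
and standardized outcomes are jointly multivariate normal around the
cohort's geometric-mean composition; wave-2 variables follow the linear
structural equations of a cross-lagged panel model with configurable
standardized autoregressive (tracking) and cross-lagged coefficients,
plus correlated concurrent residuals; ILR coordinates are mapped back
to minutes/day through the inverse ILR transform.  Effects are
specified on standardized scales and mapped to raw units afterwards, so
published standardized coefficients can be injected directly; residual
variances are budgeted so every structural variable has unit marginal
variance, making the generating standardized coefficients equal to the
injected values.

The generator also produces epoch-level acceleration traces matching a
target composition (for round-trip tests of the classification stage)
and injects the exclusion-cascade missingness pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coda
from .accel import EpochSeries

__all__ = [
    "GeneratorParams",
    "generate_cohort",
    "generate_epoch_traces",
    "inject_missingness",
    "W1_CENTRE_MIN",
    "W2_CENTRE_MIN",
]

#: Geometric-mean daily composition anchors (min/day, V/M/L/SB/Sl) at each
#: wave; re-closed to 1440 before use.
W1_CENTRE_MIN = (10.0, 55.0, 346.0, 512.0, 518.0)
W2_CENTRE_MIN = (13.0, 54.0, 294.0, 537.0, 543.0)

_ILRS = ("ilr1", "ilr2", "ilr3", "ilr4")
_OUTS = ("fmi", "ffmi", "aerobic", "motorfit", "muscular")  # motorfit: higher=better
_W1_VARS = _ILRS + _OUTS


def _default_w1_correlation() -> np.ndarray:
    """Correlation of the 9 standardized wave-1 variables
    (ilr1..ilr4, fmi, ffmi, aerobic, motorfit, muscular)."""
    R = np.eye(9)
    pairs = {
        # within the composition
        ("ilr1", "ilr2"): 0.25, ("ilr1", "ilr3"): 0.10, ("ilr1", "ilr4"): 0.00,
        ("ilr2", "ilr3"): 0.20, ("ilr2", "ilr4"): 0.10, ("ilr3", "ilr4"): 0.15,
        # behaviours with outcomes
        ("ilr1", "fmi"): -0.30, ("ilr2", "fmi"): -0.19, ("ilr4", "fmi"): 0.23,
        ("ilr1", "ffmi"): 0.10,
        ("ilr1", "aerobic"): 0.25, ("ilr2", "aerobic"): 0.15, ("ilr4", "aerobic"): 0.10,
        ("ilr1", "motorfit"): 0.15,
        ("ilr1", "muscular"): 0.20,
        # among outcomes
        ("fmi", "ffmi"): 0.30, ("fmi", "aerobic"): -0.25, ("fmi", "motorfit"): -0.20,
        ("fmi", "muscular"): -0.15, ("ffmi", "aerobic"): 0.10,
        ("ffmi", "motorfit"): 0.10, ("ffmi", "muscular"): 0.20,
        ("aerobic", "motorfit"): 0.30, ("aerobic", "muscular"): 0.30,
        ("motorfit", "muscular"): 0.30,
    }
    idx = {v: i for i, v in enumerate(_W1_VARS)}
    for (a, b), r in pairs.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R


def _default_w2_residual_correlation() -> np.ndarray:
    """Concurrent residual correlations among the 9 wave-2 variables."""
    R = np.eye(9)
    pairs = {
        ("ilr1", "fmi"): -0.25, ("ilr2", "fmi"): -0.10, ("ilr4", "fmi"): 0.15,
        ("ilr1", "aerobic"): 0.20, ("ilr1", "muscular"): 0.15,
        ("fmi", "ffmi"): 0.25,
        ("aerobic", "motorfit"): 0.20, ("aerobic", "muscular"): 0.20,
        ("motorfit", "muscular"): 0.20,
    }
    idx = {v: i for i, v in enumerate(_W1_VARS)}
    for (a, b), r in pairs.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R


@dataclass
class GeneratorParams:
    """All dials of the synthetic cohort; defaults are the study conditions.

    Standardized structural coefficients (tracking, cross-lags,
    concurrent correlations) are the published effect sizes where the
    source prints them; scale anchors (composition centres, outcome
    means/SDs, covariate distributions) follow the cohort's descriptive
    table where internally consistent, otherwise documented choices.
    """

    n: int = 231
    seed: int = 0

    # wave-1 composition centre and ILR coordinate scales
    w1_centre_min: tuple = W1_CENTRE_MIN
    w2_centre_min: tuple = W2_CENTRE_MIN
    ilr_sd: tuple = (0.45, 0.30, 0.20, 0.16)
    w1_correlation: np.ndarray = field(default_factory=_default_w1_correlation)

    # standardized structural coefficients, wave-1 -> wave-2
    tracking: dict = field(
        default_factory=lambda: {"ilr1": 0.19, "ilr2": 0.21, "ilr3": 0.08, "ilr4": 0.17}
    )
    outcome_tracking: dict = field(
        default_factory=lambda: {
            "fmi": 0.50, "ffmi": 0.50, "aerobic": 0.40, "motorfit": 0.30,
            "muscular": 0.40,
        }
    )
    cross_outcome_to_ilr: dict = field(
        default_factory=lambda: {
            ("fmi", "ilr1"): -0.22,
            ("fmi", "ilr3"): -0.19,
            ("aerobic", "ilr3"): -0.22,
        }
    )
    cross_ilr_to_outcome: dict = field(default_factory=dict)  # null by default
    sex_effects_w2: dict = field(
        default_factory=lambda: {"ilr1": -0.10, "fmi": 0.10, "aerobic": -0.10}
    )
    w2_residual_correlation: np.ndarray = field(
        default_factory=_default_w2_residual_correlation
    )

    # raw-unit anchors: mean/SD per wave for each outcome
    outcome_scale: dict = field(
        default_factory=lambda: {
            "fmi": ((4.1, 0.9), (3.6, 1.9)),
            "ffmi": ((11.6, 1.0), (13.5, 1.1)),
            "aerobic": ((15.8, 1.4), (17.1, 2.5)),
            # 4x10-m shuttle seconds; raw value = mean - sd * motorfit z
            "motor_seconds": ((13.5, 1.2), (11.5, 1.0)),
            "muscular": ((0.0, 1.0), (0.0, 1.0)),
        }
    )

    # covariates
    p_girl: float = 0.5
    age_w1: tuple = (4.5, 0.1)
    age_w2: tuple = (9.6, 0.1)
    p_university: float = 0.708
    p_intervention: float = 0.5
    energy_kcal: tuple = ((1350.0, 200.0), (1800.0, 250.0))

    # anthropometrics (mean, sd) per wave
    height_cm: tuple = ((107.6, 4.2), (139.7, 6.3))
    weight_kg: tuple = ((18.3, 2.5), (33.5, 7.1))

    # exclusion cascade counts (accelerometer, body comp, fitness)
    exclusion_counts: tuple = (9, 12, 9)

    # distribution of the number of valid accelerometer days (1..7)
    valid_day_probs: tuple = (0.02, 0.02, 0.06, 0.10, 0.20, 0.30, 0.30)


def _structural_wave2(params: GeneratorParams, z1: np.ndarray, sex_std: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Standardized wave-2 variables from the linear structural equations,
    with residual variances budgeted so each has unit marginal variance."""
    idx = {v: i for i, v in enumerate(_W1_VARS)}
    q = np.zeros((9, 9))  # coefficient matrix: wave2 var x wave1 var
    sex_coef = np.zeros(9)
    for k, t in params.tracking.items():
        q[idx[k], idx[k]] = t
    for k, t in params.outcome_tracking.items():
        q[idx[k], idx[k]] = t
    for (o, k), c in params.cross_outcome_to_ilr.items():
        q[idx[k], idx[o]] = c
    for (k, o), c in params.cross_ilr_to_outcome.items():
        q[idx[o], idx[k]] = c
    for v, c in params.sex_effects_w2.items():
        sex_coef[idx[v]] = c

    R1 = np.asarray(params.w1_correlation, dtype=float)
    explained = np.einsum("ij,jk,ik->i", q, R1, q) + sex_coef**2
    if np.any(explained > 1.0 + 1e-12):
        raise ValueError("structural coefficients imply variance > 1")
    resid_sd = np.sqrt(np.clip(1.0 - explained, 0.0, None))
    Rr = np.asarray(params.w2_residual_correlation, dtype=float)
    resid_cov = Rr * np.outer(resid_sd, resid_sd)
    evals, evecs = np.linalg.eigh(resid_cov)
    if evals.min() < -1e-8:
        raise ValueError("residual covariance is not positive semi-definite")
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))
    e = rng.standard_normal((z1.shape[0], 9)) @ L.T
    return z1 @ q.T + np.outer(sex_std, sex_coef) + e


def generate_cohort(params: GeneratorParams | None = None) -> pd.DataFrame:
    """Draw a complete synthetic cohort table (one row per participant).

    Deterministic under a fixed seed.  All validity/completeness flags
    start True; apply :func:`inject_missingness` to create the exclusion
    cascade.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)
    n = params.n
    R1 = np.asarray(params.w1_correlation, dtype=float)
    np.linalg.cholesky(R1)  # raises if not positive definite

    # covariates
    sex = rng.binomial(1, params.p_girl, n)
    sex_std = (sex - params.p_girl) / np.sqrt(params.p_girl * (1 - params.p_girl))
    age1 = rng.normal(*params.age_w1, n)
    age2 = rng.normal(*params.age_w2, n)
    matedu = rng.binomial(1, params.p_university, n)
    group = rng.binomial(1, params.p_intervention, n)

    z1 = rng.multivariate_normal(np.zeros(9), R1, size=n, method="cholesky")
    z2 = _structural_wave2(params, z1, sex_std, rng)

    mu1 = coda.ilr_transform(coda.closure(np.asarray(params.w1_centre_min)))
    mu2 = coda.ilr_transform(coda.closure(np.asarray(params.w2_centre_min)))
    sd = np.asarray(params.ilr_sd)
    ilr_w1 = mu1 + sd * z1[:, :4]
    ilr_w2 = mu2 + sd * z2[:, :4]
    comp_w1 = coda.ilr_inverse(ilr_w1)
    comp_w2 = coda.ilr_inverse(ilr_w2)

    df = pd.DataFrame({"id": [f"P{i:04d}" for i in range(n)]})
    df["sex"] = sex
    df["age_w1"] = age1
    df["age_w2"] = age2
    df["maternal_edu"] = matedu
    df["group"] = group
    for j, p in enumerate(("vpa", "mpa", "lpa", "sb", "sleep")):
        df[f"{p}_w1"] = comp_w1[:, j]
        df[f"{p}_w2"] = comp_w2[:, j]

    idx = {v: i for i, v in enumerate(_W1_VARS)}
    for wave, z in (("w1", z1), ("w2", z2)):
        w = 0 if wave == "w1" else 1
        for o in ("fmi", "ffmi", "aerobic", "muscular"):
            mean, s = params.outcome_scale[o][w]
            df[f"{o}_{wave}"] = mean + s * z[:, idx[o]]
        mean, s = params.outcome_scale["motor_seconds"][w]
        df[f"motor_{wave}"] = mean - s * z[:, idx["motorfit"]]

    # anthropometrics and strength raw measures, loosely tied to the
    # structural variables (FFMI drives weight; muscular drives strength)
    for w, wave in enumerate(("w1", "w2")):
        hm, hs = params.height_cm[w]
        wm, ws = params.weight_kg[w]
        zh = rng.normal(0, 1, n)
        df[f"height_cm_{wave}"] = hm + hs * zh
        zw = 0.5 * zh + 0.4 * z1[:, idx["ffmi"]] + 0.3 * rng.normal(0, 1, n)
        df[f"weight_kg_{wave}"] = np.maximum(wm + ws * zw, 0.5 * wm)
        zm = (z1 if wave == "w1" else z2)[:, idx["muscular"]]
        grip_mean, grip_sd = (8.5, 1.8) if wave == "w1" else (16.0, 3.0)
        jump_mean, jump_sd = (80.0, 15.0) if wave == "w1" else (120.0, 20.0)
        df[f"grip_kg_{wave}"] = np.maximum(
            grip_mean + grip_sd * (0.8 * zm + 0.6 * rng.normal(0, 1, n)), 1.0
        )
        df[f"longjump_cm_{wave}"] = np.maximum(
            jump_mean + jump_sd * (0.8 * zm + 0.6 * rng.normal(0, 1, n)), 10.0
        )
        em, es = params.energy_kcal[w]
        df[f"energy_kcal_{wave}"] = np.maximum(em + es * rng.normal(0, 1, n), 300.0)

    probs = np.asarray(params.valid_day_probs)
    for wave in ("w1", "w2"):
        df[f"n_valid_days_{wave}"] = rng.choice(np.arange(1, 8), size=n, p=probs / probs.sum())
        df[f"accel_valid_{wave}"] = True
    df["bodycomp_complete"] = True
    df["fitness_complete"] = True
    return df


def inject_missingness(
    cohort: pd.DataFrame,
    counts: tuple[int, int, int] = (9, 12, 9),
    seed: int = 0,
    overlapping: bool = False,
) -> pd.DataFrame:
    """Flag participants for the three-step exclusion cascade.

    By default the three flagged sets (insufficient accelerometer data,
    incomplete body composition, incomplete fitness) are disjoint, so
    the cascade removes exactly ``sum(counts)`` participants; in
    ``overlapping`` mode each set is drawn independently.
    """
    df = cohort.copy()
    rng = np.random.default_rng(seed)
    n = len(df)
    if sum(counts) > n:
        raise ValueError("more exclusions requested than participants")
    if overlapping:
        sets = [rng.choice(n, size=c, replace=False) for c in counts]
    else:
        chosen = rng.choice(n, size=sum(counts), replace=False)
        sets = np.split(chosen, np.cumsum(counts)[:-1])
    cols = ("accel_valid_w2", "bodycomp_complete", "fitness_complete")
    values = (False, False, False)
    for sel, col, val in zip(sets, cols, values):
        df.iloc[sel, df.columns.get_loc(col)] = val
    return df


def generate_epoch_traces(
    target,
    epoch_len: float = 5.0,
    seed: int = 0,
    cut_edges: tuple[float, float, float] = (35.0, 200.0, 700.0),
    vpa_upper: float = 1000.0,
) -> EpochSeries:
    """Build a one-day epoch series whose classification reproduces the
    target composition exactly at epoch resolution.

    Epoch counts per behaviour are allocated by largest remainder so
    they sum to a full day; magnitudes are drawn uniformly inside each
    behaviour's intensity band (sleep epochs get sub-sedentary
    magnitudes and the sleep flag).  Diurnal patterning and bout
    structure are deliberately not modelled.
    """
    rng = np.random.default_rng(seed)
    target = coda._as_parts(target)
    per_min = 60.0 / epoch_len
    day_epochs = int(round(1440 * per_min))
    exact = target * per_min * (day_epochs / (target.sum() * per_min))
    counts = np.floor(exact).astype(int)
    rem = exact - counts
    short = day_epochs - counts.sum()
    counts[np.argsort(rem)[::-1][:short]] += 1

    sb_u, lpa_u, mpa_u = cut_edges
    bands = {
        "vigorous": (mpa_u, vpa_upper),
        "moderate": (lpa_u, mpa_u),
        "light": (sb_u, lpa_u),
        "sedentary": (0.0, sb_u),
        "sleep": (0.0, sb_u),
    }
    mags, sleep_flags = [], []
    for part, c in zip(coda.PARTS, counts):
        lo, hi = bands[part]
        mags.append(rng.uniform(lo, hi, c))
        sleep_flags.append(np.full(c, part == "sleep"))
    magnitude = np.concatenate(mags)
    sleep = np.concatenate(sleep_flags)
    return EpochSeries(
        magnitude=magnitude,
        wear=np.ones(day_epochs, dtype=bool),
        sleep=sleep,
        day=np.zeros(day_epochs, dtype=int),
        epoch_len=epoch_len,
    )
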