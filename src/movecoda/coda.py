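"""Compositional geometry for 5-part daily time-use data.

A day is partitioned into vigorous physical activity (VPA), moderate
physical activity (MPA), light physical activity (LPA), sedentary
behaviour (SB) and sleep, expressed in minutes per day.  Such a vector
carries only relative information: the analysis therefore works in the
Aitchison simplex, using an isometric log-ratio (ILR) coordinate system
built from the sequential binary partition

    V | M,L,SB,Sl   ->  ilr1  (VPA against the geometric mean of the rest)
    M | L,SB,Sl     ->  ilr2
    L | SB,Sl       ->  ilr3
    SB | Sl         ->  ilr4

so that ilr1 captures the effect of raising VPA while proportionally
lowering every other behaviour, and so on down the pivot.  The module
provides closure, the ILR map and its inverse, compositional
descriptives (geometric-mean composition, variation matrix, Aitchison
distance), amalgamation and ternary coordinates for display, and the
proportional one-to-remaining reallocation used by the isotemporal
substitution predictor.

All operations accept a single composition (length-5 sequence) or a
stack of compositions (``(n, 5)`` array) and are vectorised with numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PARTS",
    "DAY_MINUTES",
    "Composition",
    "ilr_basis",
    "closure",
    "replace_zeros",
    "ilr_transform",
    "ilr_inverse",
    "geometric_mean_composition",
    "variation_matrix",
    "aitchison_distance",
    "amalgamate",
    "ternary_coordinates",
    "reallocate_proportional",
]

#: Canonical part order: vigorous, moderate, light, sedentary, sleep.
PARTS = ("vigorous", "moderate", "light", "sedentary", "sleep")

#: Minutes in a day; the default closure total.
DAY_MINUTES = 1440.0

_D = len(PARTS)


class ZeroPartError(ValueError):
    """A part is non-positive; log-ratios are undefined.

    Callers holding genuinely observed zeros (possible for VPA at daily
    resolution) should apply :func:`replace_zeros` before closure.
    """


@dataclass(frozen=True)
class Composition:
    """A closed 5-part daily time-use composition in minutes/day."""

    vigorous: float
    moderate: float
    light: float
    sedentary: float
    sleep: float
    total_minutes: float = DAY_MINUTES

    def __post_init__(self) -> None:
        arr = self.to_array()
        if np.any(arr <= 0):
            raise ZeroPartError(
                "all parts must be strictly positive; use replace_zeros() "
                "for observed zeros before constructing a Composition"
            )
        if abs(arr.sum() - self.total_minutes) > 1e-9:
            raise ValueError(
                f"parts sum to {arr.sum():.12g}, expected {self.total_minutes}; "
                "use closure() to construct from unnormalised parts"
            )

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.vigorous, self.moderate, self.light, self.sedentary, self.sleep],
            dtype=float,
        )

    @classmethod
    def from_array(cls, parts, total_minutes: float = DAY_MINUTES) -> "Composition":
        parts = closure(parts, total_minutes)
        return cls(*parts, total_minutes=total_minutes)


def _as_parts(x) -> np.ndarray:
    if isinstance(x, Composition):
        return x.to_array()
    arr = np.asarray(x, dtype=float)
    if arr.shape[-1] != _D:
        raise ValueError(f"expected {_D} parts on the last axis, got shape {arr.shape}")
    return arr


def ilr_basis() -> np.ndarray:
    """Orthonormal (5, 4) contrast matrix of the pivot partition.

    Column k is the clr-space direction of the k-th balance; ilr = clr @ V.
    """
    V = np.zeros((_D, _D - 1))
    for k in range(_D - 1):
        r = _D - k - 1  # parts in the denominator group
        c = np.sqrt(r / (r + 1.0))
        V[k, k] = c
        V[k + 1 :, k] = -c / r
    return V


_BASIS = ilr_basis()


def closure(parts, total: float = DAY_MINUTES) -> np.ndarray:
    """Rescale strictly positive parts to sum to ``total``."""
    arr = _as_parts(parts)
    if total <= 0:
        raise ValueError("total must be positive")
    if np.any(arr <= 0):
        raise ZeroPartError("closure requires strictly positive parts")
    return arr * (total / arr.sum(axis=-1, keepdims=True))


def replace_zeros(parts, floor: float = 1.0) -> np.ndarray:
    """Multiplicative zero replacement with a configurable floor (min/day).

    Zero parts are set to ``floor`` and the non-zero parts are shrunk
    proportionally so the row total is preserved.  The default floor of
    1 min/day is the smallest meaningful unit at daily resolution.
    """
    arr = _as_parts(parts).copy()
    zero = arr <= 0
    if not np.any(zero):
        return arr
    totals = arr.sum(axis=-1, keepdims=True)
    n_zero = zero.sum(axis=-1, keepdims=True)
    pos_total = np.where(zero, 0.0, arr).sum(axis=-1, keepdims=True)
    shrink = (totals - floor * n_zero) / pos_total
    out = np.where(zero, floor, arr * shrink)
    if np.any(out <= 0):
        raise ZeroPartError("floor too large for this composition")
    return out


def ilr_transform(parts) -> np.ndarray:
    """Map composition(s) to the 4 pivot ILR coordinates.

    Scale-invariant: closure (or any positive rescaling) leaves the
    result unchanged.  The equal-parts composition maps to the origin.
    """
    arr = _as_parts(parts)
    if np.any(arr <= 0):
        raise ZeroPartError("ilr_transform requires strictly positive parts")
    logx = np.log(arr)
    clr = logx - logx.mean(axis=-1, keepdims=True)
    return clr @ _BASIS


def ilr_inverse(coords, total: float = DAY_MINUTES) -> np.ndarray:
    """Map ILR coordinate(s) back to a composition closed to ``total``."""
    z = np.asarray(coords, dtype=float)
    if z.shape[-1] != _D - 1:
        raise ValueError(f"expected {_D - 1} coordinates, got shape {z.shape}")
    clr = z @ _BASIS.T
    raw = np.exp(clr - clr.max(axis=-1, keepdims=True))  # overflow guard
    return closure(raw, total)


def geometric_mean_composition(samples, total: float = DAY_MINUTES) -> np.ndarray:
    """Per-part geometric mean across samples, closed to ``total``.

    This is the compositional centre: the normalised mean to the average
    day duration.
    """
    arr = np.atleast_2d(_as_parts(samples))
    if arr.shape[0] < 1:
        raise ValueError("need at least one sample")
    gm = np.exp(np.log(arr).mean(axis=0))
    return closure(gm, total)


def variation_matrix(samples, ddof: int = 1) -> np.ndarray:
    """Pairwise log-ratio variances; the compositional covariance summary.

    Entry (i, j) is Var[ln(part_i / part_j)] across samples.  Small
    entries indicate that two behaviours co-vary proportionally.  The
    matrix is symmetric with a zero diagonal and is invariant to
    rescaling any sample by a positive constant.
    """
    arr = np.atleast_2d(_as_parts(samples))
    if arr.shape[0] < 2:
        raise ValueError("variation matrix requires at least 2 samples")
    logx = np.log(arr)
    diffs = logx[:, :, None] - logx[:, None, :]
    return diffs.var(axis=0, ddof=ddof)


def aitchison_distance(a, b) -> float:
    """Compositional distance: Euclidean distance in ILR coordinates."""
    za = ilr_transform(a)
    zb = ilr_transform(b)
    return float(np.linalg.norm(za - zb, axis=-1))


def amalgamate(parts, grouping: dict[str, list[str]] | None = None) -> np.ndarray:
    """Collapse the 5 parts into 3 groups (for ternary display), closed to 1.

    ``grouping`` maps each group label to the parts it absorbs; the
    default is {sleep} | {sedentary} | {active = VPA+MPA+LPA}.  Group
    order follows insertion order of the mapping.
    """
    if grouping is None:
        grouping = {
            "sleep": ["sleep"],
            "sedentary": ["sedentary"],
            "active": ["vigorous", "moderate", "light"],
        }
    if len(grouping) != 3:
        raise ValueError("grouping must define exactly 3 groups")
    members = [m for group in grouping.values() for m in group]
    if sorted(members) != sorted(PARTS):
        raise ValueError("grouping must cover each of the 5 parts exactly once")
    arr = _as_parts(parts)
    idx = {p: i for i, p in enumerate(PARTS)}
    groups = np.stack(
        [arr[..., [idx[m] for m in group]].sum(axis=-1) for group in grouping.values()],
        axis=-1,
    )
    return groups / groups.sum(axis=-1, keepdims=True)


def ternary_coordinates(p) -> np.ndarray:
    """Barycentric-to-Cartesian map onto the unit-side equilateral triangle.

    Vertices: part 1 -> (0, 0), part 2 -> (1, 0), part 3 -> (0.5, sqrt(3)/2).
    """
    arr = np.asarray(p, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("ternary coordinates need a 3-part composition")
    if np.any(np.abs(arr.sum(axis=-1) - 1.0) > 1e-9):
        raise ValueError("parts must sum to 1")
    x = arr[..., 1] + 0.5 * arr[..., 2]
    y = (np.sqrt(3.0) / 2.0) * arr[..., 2]
    return np.stack([x, y], axis=-1)


def reallocate_proportional(parts, target_part: str, delta: float) -> np.ndarray:
    """Move ``delta`` minutes into ``target_part``, taken proportionally
    from the remaining four behaviours (the one-vs-remaining reallocation
    that the first pivot coordinate parameterises when the target is VPA).

    The day total is preserved; when the target is ``vigorous`` only the
    first ILR coordinate changes.
    """
    if target_part not in PARTS:
        raise ValueError(f"unknown part {target_part!r}")
    arr = _as_parts(parts).copy()
    i = PARTS.index(target_part)
    total = arr.sum(axis=-1, keepdims=True)
    new_target = arr[..., i] + delta
    scale = (total.squeeze(-1) - new_target) / (total.squeeze(-1) - arr[..., i])
    out = arr * scale[..., None]
    out[..., i] = new_target
    if np.any(out <= 0):
        raise ValueError(f"delta of {delta} min exhausts a behaviour")
    return out
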