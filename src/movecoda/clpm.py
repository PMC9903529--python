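"""Cross-lagged panel models, compositional mediation, and the
minutes-per-day reallocation predictor.

These are the concrete analyses built on :mod:`movecoda.pathmodel` and
:mod:`movecoda.coda`:

* a two-wave cross-lagged panel model (CLPM) relating the four ILR
  coordinates of the daily time-use composition to either the body
  composition outcomes (FMI, FFMI) or the physical-fitness outcomes
  (aerobic, motor, muscular), with same-coordinate autoregression for
  the ILRs, fully free cross-lags between behaviours and outcomes,
  covariate paths to all follow-up variables, and saturated baseline /
  residual covariance blocks;
* an X -> M -> Y mediation model in which a baseline ILR coordinate acts
  through its follow-up value on a follow-up outcome, adjusted for the
  remaining baseline coordinates so the full 24-h composition is held;
* an isotemporal-substitution predictor translating the mediation
  coefficients into the expected outcome change when a given number of
  minutes per day is reallocated to VPA proportionally from the other
  behaviours.

Dataset convention: one row per participant with columns
``ilr1_w1..ilr4_w1, ilr1_w2..ilr4_w2``, outcome columns suffixed
``_w1``/``_w2`` (motor fitness sign-flipped so higher = better), and
covariate columns.  :func:`build_model_frame` derives this frame from a
cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coda
from .pathmodel import FittedModel, ModelSpec, fit_ml, model_df, satorra_bentler_scale

__all__ = [
    "ClpmConfig",
    "OUTCOME_SETS",
    "DEFAULT_COVARIATES",
    "build_model_frame",
    "build_clpm_spec",
    "run_clpm",
    "build_mediation_spec",
    "fit_mediation",
    "run_mediation",
    "MediationResult",
    "predict_reallocation",
    "ReallocationCurve",
]

ILR_NAMES = ("ilr1", "ilr2", "ilr3", "ilr4")

OUTCOME_SETS = {
    "bodycomp": ("fmi", "ffmi"),
    "fitness": ("aerobic", "motor", "muscular"),
}

DEFAULT_COVARIATES = ("sex", "age_w1", "age_w2", "maternal_edu", "group")


@dataclass(frozen=True)
class ClpmConfig:
    """Configuration of one cross-lagged panel model."""

    outcome_set: str = "bodycomp"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    include_energy: bool = False  # energy-intake sensitivity adjustment
    lag_structure: str = "same_coordinate"  # or "saturated": free cross-ILR lags

    @property
    def outcomes(self) -> tuple[str, ...]:
        try:
            return OUTCOME_SETS[self.outcome_set]
        except KeyError:
            raise ValueError(f"unknown outcome set {self.outcome_set!r}") from None

    @property
    def covariate_list(self) -> list[str]:
        covs = list(self.covariates)
        if self.include_energy:
            covs += ["energy_kcal_w1", "energy_kcal_w2"]
        return covs


def build_model_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive the modelling frame from a cohort table.

    Computes the four ILR coordinates from the minutes-per-day
    composition at each wave, carries outcomes and covariates over, and
    sign-flips motor fitness (4x10-m seconds) so that higher values mean
    better fitness for every outcome.
    """
    out = pd.DataFrame(index=cohort.index)
    for wave in ("w1", "w2"):
        comp_cols = [f"{p}_{wave}" for p in ("vpa", "mpa", "lpa", "sb", "sleep")]
        parts = coda.replace_zeros(cohort[comp_cols].to_numpy(dtype=float))
        z = coda.ilr_transform(parts)
        for k, name in enumerate(ILR_NAMES):
            out[f"{name}_{wave}"] = z[:, k]
        for o in ("fmi", "ffmi", "aerobic", "muscular"):
            col = f"{o}_{wave}"
            if col in cohort.columns:
                out[col] = cohort[col].to_numpy(dtype=float)
        if f"motor_{wave}" in cohort.columns:
            out[f"motor_{wave}"] = -cohort[f"motor_{wave}"].to_numpy(dtype=float)
        if f"energy_kcal_{wave}" in cohort.columns:
            out[f"energy_kcal_{wave}"] = cohort[f"energy_kcal_{wave}"].to_numpy(float)
    for c in ("sex", "age_w1", "age_w2", "maternal_edu", "group"):
        out[c] = cohort[c].to_numpy(dtype=float)
    return out


def build_clpm_spec(config: ClpmConfig) -> ModelSpec:
    """Assemble the CLPM specification.

    Structure: (i) same-coordinate ILR autoregression; (ii) free lags
    from every baseline ILR to every follow-up outcome, every baseline
    outcome to every follow-up ILR, and every baseline outcome to every
    follow-up outcome; (iii) no lags between *different* ILR
    coordinates (those 12 omitted paths are what give the model its
    12 degrees of freedom); (iv) covariate paths to every follow-up
    variable; (v) saturated covariances within the baseline-plus-
    covariate block and among follow-up residuals.
    """
    outcomes = config.outcomes
    covs = config.covariate_list
    w1_ilrs = [f"{k}_w1" for k in ILR_NAMES]
    w2_ilrs = [f"{k}_w2" for k in ILR_NAMES]
    w1_out = [f"{o}_w1" for o in outcomes]
    w2_out = [f"{o}_w2" for o in outcomes]
    variables = w1_ilrs + w1_out + covs + w2_ilrs + w2_out
    spec = ModelSpec(variables)

    for a, b in zip(w1_ilrs, w2_ilrs):
        spec.add_path(b, a)  # autoregressive tracking
    if config.lag_structure == "saturated":
        for a in w1_ilrs:
            for b in w2_ilrs:
                if a[:4] != b[:4]:
                    spec.add_path(b, a)
    elif config.lag_structure != "same_coordinate":
        raise ValueError(f"unknown lag structure {config.lag_structure!r}")
    for a in w1_ilrs:
        for y in w2_out:
            spec.add_path(y, a)
    for x in w1_out:
        for b in w2_ilrs:
            spec.add_path(b, x)
        for y in w2_out:
            spec.add_path(y, x)
    for c in covs:
        for v in w2_ilrs + w2_out:
            spec.add_path(v, c)
    exog = w1_ilrs + w1_out + covs
    for i, a in enumerate(exog):
        for b in exog[i + 1 :]:
            spec.add_cov(a, b)
    endo = w2_ilrs + w2_out
    for i, a in enumerate(endo):
        for b in endo[i + 1 :]:
            spec.add_cov(a, b)  # shared residual covariance
    return spec


@dataclass
class ClpmResult:
    fitted: FittedModel
    config: ClpmConfig
    report: pd.DataFrame  # lagged + concurrent coefficients, std, p, significance

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.report[self.report["p"] < alpha]


def run_clpm(
    dataset: pd.DataFrame,
    config: ClpmConfig | None = None,
    robust: bool = True,
) -> ClpmResult:
    """Fit the CLPM to a modelling frame and tabulate its coefficients.

    The report contains one row per lagged path and per follow-up
    residual covariance, with raw estimate, SE, standardized coefficient
    and Wald p-value; ``significant()`` mirrors the convention of
    displaying only paths with p < 0.05.  When ``robust`` the
    Satorra-Bentler scaled chi-square is computed from the raw data.
    """
    config = config or ClpmConfig()
    spec = build_clpm_spec(config)
    missing = [v for v in spec.variables if v not in dataset.columns]
    if missing:
        raise ValueError(f"dataset lacks modelled variables: {missing}")
    frame = dataset[spec.variables].dropna()
    n = len(frame)
    if n <= spec.n_free:
        raise ValueError(
            f"n = {n} participants cannot identify {spec.n_free} free parameters"
        )
    S = frame.cov()
    fitted = fit_ml(S, n, spec)
    if robust and fitted.df > 0:
        satorra_bentler_scale(frame, fitted)

    std = fitted.standardized()
    pvals = fitted.p_values()
    w1_vars = {f"{k}_w1" for k in ILR_NAMES} | {f"{o}_w1" for o in config.outcomes}
    rows = []
    for prm in spec.parameters():
        if not prm.free:
            continue
        lagged = prm.kind == "path" and prm.lhs.endswith("_w2") and prm.rhs in w1_vars
        concurrent = (
            prm.kind == "cov" and prm.lhs != prm.rhs
            and prm.lhs.endswith("_w2") and prm.rhs.endswith("_w2")
        )
        if not (lagged or concurrent):
            continue
        lab = prm.label
        rows.append(
            {
                "parameter": lab,
                "type": "lagged" if lagged else "concurrent",
                "estimate": fitted.estimates[lab],
                "se": fitted.se[lab],
                "beta": std[lab],
                "p": pvals[lab],
                "significant": pvals[lab] < 0.05,
            }
        )
    report = pd.DataFrame(rows)
    return ClpmResult(fitted=fitted, config=config, report=report)


# ---------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------


def build_mediation_spec(
    x: str,
    m: str,
    y: str,
    covariates: list[str],
) -> ModelSpec:
    """Two-equation recursive mediation model: M ~ X + Z;  Y ~ M + X + Z.

    The adjustment set Z (covariates plus the other baseline ILR
    coordinates) enters both equations; exogenous covariances are
    saturated, so the model is just-identified (df = 0) and its path
    estimates coincide with equation-wise least squares.
    """
    variables = [x] + list(covariates) + [m, y]
    spec = ModelSpec(variables)
    for z in [x] + list(covariates):
        spec.add_path(m, z)
        spec.add_path(y, z)
    spec.add_path(y, m)
    exog = [x] + list(covariates)
    for i, a in enumerate(exog):
        for b in exog[i + 1 :]:
            spec.add_cov(a, b)
    return spec


@dataclass
class MediationResult:
    """Decomposition of the X -> Y effect through mediator M.

    ``a`` is X->M, ``b`` is M->Y given X, ``c_prime`` the direct path;
    indirect = a*b with a delta-method SE; total = c_prime + a*b exactly.
    ``standardized`` holds the same decomposition on z-scored variables
    (the scale on which coefficients are reported); raw-unit
    coefficients drive the reallocation predictor.
    """

    x: str
    m: str
    y: str
    a: float
    b: float
    c_prime: float
    indirect: float
    total: float
    se: dict[str, float]
    p: dict[str, float]
    standardized: dict[str, float]
    n: int
    fitted: FittedModel
    bootstrap_ci: dict[str, tuple[float, float]] | None = None

    def summary(self) -> str:
        lines = [
            f"mediation {self.x} -> {self.m} -> {self.y} (n = {self.n})",
            f"  a (X->M):      {self.a:+.4f} (se {self.se['a']:.4f}, p {self.p['a']:.4f})",
            f"  b (M->Y):      {self.b:+.4f} (se {self.se['b']:.4f}, p {self.p['b']:.4f})",
            f"  direct c':     {self.c_prime:+.4f} (se {self.se['c_prime']:.4f}, p {self.p['c_prime']:.4f})",
            f"  indirect a*b:  {self.indirect:+.4f} (se {self.se['indirect']:.4f}, p {self.p['indirect']:.4f})",
            f"  total:         {self.total:+.4f} (se {self.se['total']:.4f}, p {self.p['total']:.4f})",
            f"  standardized indirect: {self.standardized['indirect']:+.4f}",
        ]
        if self.bootstrap_ci:
            ci = self.bootstrap_ci["indirect"]
            lines.append(f"  bootstrap 95% CI (indirect): [{ci[0]:+.4f}, {ci[1]:+.4f}]")
        return "\n".join(lines)


def _mediation_effects(frame: pd.DataFrame, spec: ModelSpec, x: str, m: str, y: str):
    """Fit and extract (a, b, c', SEs incl. delta-method composites)."""
    from scipy import stats as _st

    fitted = fit_ml(frame.cov(), len(frame), spec, compute_indices=False)
    a = fitted.estimates[f"{m} ~ {x}"]
    b = fitted.estimates[f"{y} ~ {m}"]
    c = fitted.estimates[f"{y} ~ {x}"]
    labels = fitted.free_labels
    V = fitted.vcov
    ia, ib, ic = (labels.index(k) for k in (f"{m} ~ {x}", f"{y} ~ {m}", f"{y} ~ {x}"))
    va, vb, vc = V[ia, ia], V[ib, ib], V[ic, ic]
    # delta method: grad of a*b is (b, a); total adds c' with unit weight
    var_ind = b * b * va + a * a * vb + 2 * a * b * V[ia, ib]
    var_tot = var_ind + vc + 2 * (b * V[ia, ic] + a * V[ib, ic])
    se = {
        "a": float(np.sqrt(va)),
        "b": float(np.sqrt(vb)),
        "c_prime": float(np.sqrt(vc)),
        "indirect": float(np.sqrt(max(var_ind, 0.0))),
        "total": float(np.sqrt(max(var_tot, 0.0))),
    }
    est = {"a": a, "b": b, "c_prime": c, "indirect": a * b, "total": c + a * b}
    p = {
        k: float(2 * _st.norm.sf(abs(est[k] / se[k]))) if se[k] > 0 else float("nan")
        for k in est
    }
    return fitted, est, se, p


def fit_mediation(
    dataset: pd.DataFrame,
    xv: str,
    mv: str,
    yv: str,
    adjust: list[str] | tuple[str, ...] = (),
    bootstrap: int = 0,
    seed: int | None = None,
) -> MediationResult:
    """Fit an X -> M -> Y mediation path model on named columns.

    The general engine behind :func:`run_mediation`; ``adjust`` enters
    both equations.  ``bootstrap`` > 0 adds seeded percentile bootstrap
    CIs for every effect.
    """
    adjust = list(adjust)
    cols = [xv, mv, yv] + adjust
    frame = dataset[cols].dropna()
    n = len(frame)

    cond = np.linalg.cond(frame[[xv] + adjust].cov().to_numpy())
    if cond > 1e8:
        raise ValueError(
            f"adjustment set is near-collinear (condition number {cond:.2e})"
        )

    spec = build_mediation_spec(xv, mv, yv, adjust)
    fitted, est, se, p = _mediation_effects(frame, spec, xv, mv, yv)

    zframe = (frame - frame.mean()) / frame.std(ddof=1)
    spec_z = build_mediation_spec(xv, mv, yv, adjust)
    _, est_z, se_z, p_z = _mediation_effects(zframe, spec_z, xv, mv, yv)
    standardized = dict(est_z)
    standardized.update({f"se_{k}": v for k, v in se_z.items()})
    standardized.update({f"p_{k}": v for k, v in p_z.items()})

    boot_ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = {"a": [], "b": [], "c_prime": [], "indirect": [], "total": []}
        for _ in range(bootstrap):
            bs = frame.sample(n=n, replace=True, random_state=rng.integers(2**31 - 1))
            spec_b = build_mediation_spec(xv, mv, yv, adjust)
            try:
                _, est_b, _, _ = _mediation_effects(bs, spec_b, xv, mv, yv)
            except (ValueError, np.linalg.LinAlgError):
                continue
            for k in draws:
                draws[k].append(est_b[k])
        boot_ci = {
            k: tuple(np.percentile(v, [2.5, 97.5])) for k, v in draws.items() if v
        }
        boot_se = {k: float(np.std(v, ddof=1)) for k, v in draws.items() if len(v) > 1}
        standardized["bootstrap_se_indirect_raw"] = boot_se.get("indirect", float("nan"))

    return MediationResult(
        x=xv,
        m=mv,
        y=yv,
        a=est["a"],
        b=est["b"],
        c_prime=est["c_prime"],
        indirect=est["indirect"],
        total=est["total"],
        se=se,
        p=p,
        standardized=standardized,
        n=n,
        fitted=fitted,
        bootstrap_ci=boot_ci,
    )


def run_mediation(
    dataset: pd.DataFrame,
    x: str = "ilr1",
    y: str = "fmi",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    include_other_w2_ilrs: bool = False,
    bootstrap: int = 0,
    seed: int | None = None,
) -> MediationResult:
    """Run the compositional mediation analysis for one (x, y) pair.

    ``x`` names an ILR coordinate; its baseline value is the exposure
    and its follow-up value the mediator; ``y`` names a follow-up
    outcome.  The remaining baseline ILR coordinates always join the
    adjustment set so the whole 24-h composition is controlled; the
    remaining follow-up coordinates are optional co-mediator adjusters.
    """
    if x not in ILR_NAMES:
        raise ValueError(f"exposure must be one of {ILR_NAMES}")
    xv, mv, yv = f"{x}_w1", f"{x}_w2", f"{y}_w2"
    adjust = list(covariates) + [f"{k}_w1" for k in ILR_NAMES if k != x]
    if include_other_w2_ilrs:
        adjust += [f"{k}_w2" for k in ILR_NAMES if k != x]
    return fit_mediation(
        dataset, xv, mv, yv, adjust, bootstrap=bootstrap, seed=seed
    )


# ---------------------------------------------------------------------
# reallocation predictor
# ---------------------------------------------------------------------


@dataclass
class ReallocationCurve:
    """Predicted outcome change against minutes/day reallocated to a target
    behaviour, taken proportionally from the remaining behaviours."""

    target: str
    outcome: str
    variant: str  # "total" or "indirect"
    deltas: np.ndarray
    compositions: np.ndarray  # (len(deltas), 5) minutes/day
    delta_ilr1: np.ndarray
    predicted_change: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.compositions, columns=[f"{p}_min" for p in coda.PARTS])
        df.insert(0, "delta_min", self.deltas)
        df["delta_ilr1"] = self.delta_ilr1
        df[f"predicted_change_{self.outcome}"] = self.predicted_change
        return df


def predict_reallocation(
    mediation: MediationResult,
    base,
    deltas,
    variant: str = "total",
    target: str = "vigorous",
) -> ReallocationCurve:
    """Translate mediation coefficients into minutes-per-day terms.

    For each delta on the grid the base composition is perturbed by
    moving ``delta`` minutes to the target behaviour proportionally from
    the rest, the first ILR coordinate is recomputed (the remaining
    coordinates are unchanged by construction for a VPA target), and the
    predicted outcome change is the chosen raw-unit path coefficient
    (total = c' + a*b, or indirect = a*b) times the ILR shift.  Zero
    delta maps to zero change.
    """
    if variant == "total":
        coef = mediation.total
    elif variant == "indirect":
        coef = mediation.indirect
    else:
        raise ValueError("variant must be 'total' or 'indirect'")
    base_arr = coda._as_parts(base)
    deltas = np.asarray(deltas, dtype=float)
    base_z = coda.ilr_transform(base_arr)
    comps = np.empty((len(deltas), 5))
    dz1 = np.empty(len(deltas))
    for i, d in enumerate(deltas):
        newc = coda.reallocate_proportional(base_arr, target, float(d))
        comps[i] = newc
        dz1[i] = coda.ilr_transform(newc)[0] - base_z[0]
    return ReallocationCurve(
        target=target,
        outcome=mediation.y,
        variant=variant,
        deltas=deltas,
        compositions=comps,
        delta_ilr1=dz1,
        predicted_change=coef * dz1,
    )
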