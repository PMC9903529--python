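"""Covariance-structure path modelling with normal-theory ML.

The estimator behind the cross-lagged panel and mediation models.  A
model over p observed variables is written in the usual structural form

    x = B x + e,        Cov(e) = Psi,

with B the (acyclic) matrix of directed-path coefficients and Psi the
symmetric matrix of variances and two-headed covariances; the implied
covariance is  Sigma(theta) = (I - B)^-1 Psi (I - B)^-T.  Free
parameters are estimated by minimising the ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p,

whose minimum gives the chi-square statistic T = (n - 1) F.  The module
also provides the standard approximate fit indices (CFI against the
independence baseline, RMSEA with its noncentral-chi-square confidence
interval, SRMR), the Satorra-Bentler scaling correction computed from
empirical fourth moments when raw data are available, standardized
coefficients, and expected-information standard errors.

Only observed-variable (path) models are supported: no latent factors
with multiple indicators, no mean structure, no missing-data estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "FittedModel",
    "FitIndices",
    "implied_covariance",
    "fit_ml",
    "model_df",
    "fit_indices",
    "satorra_bentler_scale",
]


@dataclass
class _Param:
    kind: str  # "path" | "cov" (cov with lhs == rhs is a variance)
    lhs: str
    rhs: str
    free: bool = True
    value: float = 0.0  # fixed value, or estimate after fitting

    @property
    def label(self) -> str:
        op = "~" if self.kind == "path" else "~~"
        return f"{self.lhs} {op} {self.rhs}"


class ModelSpec:
    """A path-model specification over named observed variables.

    Directed paths are added as ``y ~ x`` (outcome on the left), free by
    default or fixed to a value; two-headed terms as ``a ~~ b``
    (``a ~~ a`` is a variance).  Every variable automatically receives a
    free variance unless one was declared.  The directed graph must be
    acyclic (recursive models only).
    """

    def __init__(self, variables: list[str]):
        if len(set(variables)) != len(variables):
            raise ValueError("duplicate variable names")
        self.variables = list(variables)
        self._index = {v: i for i, v in enumerate(self.variables)}
        self._paths: dict[tuple[str, str], _Param] = {}
        self._covs: dict[tuple[str, str], _Param] = {}

    # -- construction -------------------------------------------------
    def add_path(self, y: str, x: str, free: bool = True, value: float = 0.0) -> None:
        self._check(y, x)
        if y == x:
            raise ValueError("a path cannot point at its own source")
        self._paths[(y, x)] = _Param("path", y, x, free, value)

    def add_cov(self, a: str, b: str, free: bool = True, value: float = 0.0) -> None:
        self._check(a, b)
        key = (a, b) if self._index[a] <= self._index[b] else (b, a)
        self._covs[key] = _Param("cov", key[0], key[1], free, value)

    def _check(self, *names: str) -> None:
        for v in names:
            if v not in self._index:
                raise ValueError(f"unknown variable {v!r}")

    def parameters(self) -> list[_Param]:
        """All parameters in canonical order (paths, variances, covariances),
        with implicit free variances filled in."""
        params = list(self._paths.values())
        for v in self.variables:
            key = (v, v)
            params.append(self._covs.get(key, _Param("cov", v, v, True, 0.0)))
        params.extend(p for (a, b), p in self._covs.items() if a != b)
        return params

    @property
    def n_free(self) -> int:
        return sum(p.free for p in self.parameters())

    def endogenous(self) -> list[str]:
        return sorted({y for (y, _x) in self._paths}, key=self._index.get)

    def predictors_of(self, y: str) -> list[str]:
        return [x for (yy, x) in self._paths if yy == y]

    def check_acyclic(self) -> None:
        order: list[str] = []
        marks: dict[str, int] = {}

        def visit(v: str) -> None:
            state = marks.get(v, 0)
            if state == 1:
                raise ValueError("directed-path set contains a cycle")
            if state == 2:
                return
            marks[v] = 1
            for x in self.predictors_of(v):
                visit(x)
            marks[v] = 2
            order.append(v)

        for v in self.variables:
            visit(v)

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        def entry(p: _Param) -> str:
            if p.free:
                return p.label
            return f"{p.lhs} {'~' if p.kind == 'path' else '~~'} {p.value}*{p.rhs}"

        return {
            "variables": list(self.variables),
            "paths": [entry(p) for p in self._paths.values()],
            "covariances": [entry(p) for p in self._covs.values()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        spec = cls(d["variables"])
        for line in d.get("paths", []):
            y, rhs = [s.strip() for s in line.split("~", 1)]
            if "*" in rhs:
                val, x = rhs.split("*", 1)
                spec.add_path(y, x.strip(), free=False, value=float(val))
            else:
                spec.add_path(y, rhs)
        for line in d.get("covariances", []):
            a, rhs = [s.strip() for s in line.split("~~", 1)]
            if "*" in rhs:
                val, b = rhs.split("*", 1)
                spec.add_cov(a, b.strip(), free=False, value=float(val))
            else:
                spec.add_cov(a, rhs)
        return spec


def model_df(spec: ModelSpec, p: int | None = None) -> int:
    """Degrees of freedom: distinct covariance moments minus free parameters."""
    p = p if p is not None else len(spec.variables)
    return p * (p + 1) // 2 - spec.n_free


@dataclass(frozen=True)
class FitIndices:
    cfi: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    chi2_baseline: float
    df_baseline: int
    scaled_chi2: float | None = None
    scaling_factor: float | None = None


@dataclass
class FittedModel:
    spec: ModelSpec
    n: int
    S: np.ndarray
    B: np.ndarray
    Psi: np.ndarray
    sigma: np.ndarray
    estimates: dict[str, float]
    se: dict[str, float]
    chi2: float
    df: int
    p_value: float
    converged: bool
    grad_norm: float
    n_iter: int
    indices: FitIndices | None = None
    free_labels: list[str] = field(default_factory=list)
    vcov: np.ndarray | None = None  # covariance of the free-parameter estimates

    def z_values(self) -> dict[str, float]:
        return {
            k: (self.estimates[k] / s if s > 0 else math.nan)
            for k, s in self.se.items()
        }

    def p_values(self) -> dict[str, float]:
        return {k: 2.0 * stats.norm.sf(abs(z)) for k, z in self.z_values().items()}

    def standardized(self) -> dict[str, float]:
        """Standardized solution: paths scaled by implied predictor/outcome
        SDs, two-headed terms converted to correlations.  Invariant to
        linear rescaling of the observed variables."""
        sd = np.sqrt(np.diag(self.sigma))
        idx = self.spec._index
        out: dict[str, float] = {}
        for p in self.spec.parameters():
            if p.kind == "path":
                out[p.label] = p.value * sd[idx[p.rhs]] / sd[idx[p.lhs]]
            elif p.lhs == p.rhs:
                out[p.label] = p.value / self.sigma[idx[p.lhs], idx[p.lhs]]
            else:
                out[p.label] = p.value / (sd[idx[p.lhs]] * sd[idx[p.rhs]])
        return out

    def summary(self) -> str:
        lines = [
            f"ML path model: {len(self.spec.variables)} variables, n = {self.n}",
            f"chi2 = {self.chi2:.4f}, df = {self.df}, p = {self.p_value:.4f}",
        ]
        if self.indices is not None:
            fi = self.indices
            lines.append(
                f"CFI = {fi.cfi:.3f}, RMSEA = {fi.rmsea:.3f} "
                f"[{fi.rmsea_ci[0]:.3f}, {fi.rmsea_ci[1]:.3f}], SRMR = {fi.srmr:.4f}"
            )
            if fi.scaled_chi2 is not None:
                lines.append(
                    f"Satorra-Bentler scaled chi2 = {fi.scaled_chi2:.4f} "
                    f"(scaling factor {fi.scaling_factor:.4f})"
                )
        std = self.standardized()
        pv = self.p_values()
        lines.append(f"{'parameter':<34}{'est':>10}{'se':>10}{'beta':>10}{'p':>10}")
        for key, est in self.estimates.items():
            lines.append(
                f"{key:<34}{est:>10.4f}{self.se.get(key, math.nan):>10.4f}"
                f"{std.get(key, math.nan):>10.4f}{pv.get(key, math.nan):>10.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------
# implied covariance and ML machinery
# ---------------------------------------------------------------------


def _matrices(spec: ModelSpec, theta: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (B, Psi) from the spec, substituting free values from
    ``theta`` (natural scale, canonical parameter order) when given."""
    p = len(spec.variables)
    idx = spec._index
    B = np.zeros((p, p))
    Psi = np.zeros((p, p))
    it = iter(theta if theta is not None else [])
    for prm in spec.parameters():
        val = next(it) if (theta is not None and prm.free) else prm.value
        i, j = idx[prm.lhs], idx[prm.rhs]
        if prm.kind == "path":
            B[i, j] = val
        else:
            Psi[i, j] = Psi[j, i] = val
    return B, Psi


def implied_covariance(spec: ModelSpec, theta: np.ndarray | None = None) -> np.ndarray:
    """Sigma(theta) = (I - B)^-1 Psi (I - B)^-T."""
    B, Psi = _matrices(spec, theta)
    p = len(spec.variables)
    A = np.linalg.solve(np.eye(p) - B, np.eye(p))
    return A @ Psi @ A.T


def _start_values(spec: ModelSpec, S: np.ndarray) -> np.ndarray:
    """Equation-wise least-squares starting values.

    Free paths from per-equation OLS on S; free variances from S (full
    for exogenous, residual for endogenous); free covariances from S for
    exogenous pairs and 0 for residual pairs.
    """
    idx = spec._index
    endo = set(spec.endogenous())
    resid_var: dict[str, float] = {}
    start_path: dict[tuple[str, str], float] = {}
    for y in endo:
        preds = spec.predictors_of(y)
        free_preds = [x for x in preds if spec._paths[(y, x)].free]
        iy = idx[y]
        contrib = 0.0
        sy = S[iy, iy]
        if free_preds:
            ix = [idx[x] for x in free_preds]
            Sxx = S[np.ix_(ix, ix)]
            Sxy = S[ix, iy]
            b = np.linalg.solve(Sxx, Sxy)
            for x, bx in zip(free_preds, b):
                start_path[(y, x)] = bx
            contrib = float(b @ Sxy)
        resid_var[y] = max(sy - contrib, 0.05 * sy)
    theta = []
    for prm in spec.parameters():
        if not prm.free:
            continue
        i, j = idx[prm.lhs], idx[prm.rhs]
        if prm.kind == "path":
            theta.append(start_path.get((prm.lhs, prm.rhs), 0.0))
        elif prm.lhs == prm.rhs:
            theta.append(resid_var[prm.lhs] if prm.lhs in endo else S[i, i])
        else:
            both_exo = prm.lhs not in endo and prm.rhs not in endo
            theta.append(S[i, j] if both_exo else 0.0)
    return np.array(theta)


def _free_layout(spec: ModelSpec):
    """Index bookkeeping for the free-parameter vector."""
    idx = spec._index
    kinds, rows, cols = [], [], []
    for prm in spec.parameters():
        if not prm.free:
            continue
        if prm.kind == "path":
            kinds.append(0)
        elif prm.lhs == prm.rhs:
            kinds.append(1)
        else:
            kinds.append(2)
        rows.append(idx[prm.lhs])
        cols.append(idx[prm.rhs])
    return np.array(kinds), np.array(rows), np.array(cols)


def _pack(theta_nat: np.ndarray, kinds: np.ndarray) -> np.ndarray:
    x = theta_nat.copy()
    x[kinds == 1] = np.log(np.maximum(theta_nat[kinds == 1], 1e-10))
    return x


def _unpack(x: np.ndarray, kinds: np.ndarray) -> np.ndarray:
    theta = x.copy()
    theta[kinds == 1] = np.exp(x[kinds == 1])
    return theta


def fit_ml(S, n: int, spec: ModelSpec, compute_indices: bool = True) -> FittedModel:
    """Fit the model to a sample covariance matrix by normal-theory ML.

    ``S`` may be an aligned ndarray or a labelled DataFrame (reindexed
    to the spec's variable order).  Raises on non-identified models
    (negative df) and reports non-convergence in the result.
    """
    if isinstance(S, pd.DataFrame):
        S = S.loc[spec.variables, spec.variables].to_numpy()
    S = np.asarray(S, dtype=float)
    p = len(spec.variables)
    if S.shape != (p, p):
        raise ValueError(f"S must be {p}x{p} aligned to the spec variables")
    df = model_df(spec, p)
    if df < 0:
        raise ValueError(f"model not identified: df = {df} < 0")
    spec.check_acyclic()
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")
    if n <= spec.n_free:
        raise ValueError(
            f"sample size n = {n} does not exceed the {spec.n_free} free parameters"
        )

    kinds, rows, cols = _free_layout(spec)
    eye = np.eye(p)

    def f_and_grad(x: np.ndarray):
        theta = _unpack(x, kinds)
        B, Psi = _matrices(spec, theta)
        A = np.linalg.solve(eye - B, eye)
        sigma = A @ Psi @ A.T
        s, logdet = np.linalg.slogdet(sigma)
        if s <= 0 or not np.isfinite(logdet):
            return 1e10 + float(np.sum(x**2)), 2.0 * x
        sigma_inv = np.linalg.inv(sigma)
        F = logdet + float(np.trace(S @ sigma_inv)) - logdet_S - p
        G = sigma_inv - sigma_inv @ S @ sigma_inv
        K_path = 2.0 * (A.T @ G @ sigma)
        H = A.T @ G @ A
        grad = np.empty_like(x)
        for k, (kd, i, j) in enumerate(zip(kinds, rows, cols)):
            if kd == 0:
                grad[k] = K_path[i, j]
            elif kd == 1:
                grad[k] = H[i, i] * theta[k]  # chain rule through log-variance
            else:
                grad[k] = 2.0 * H[i, j]
        return F, grad

    def f_only(theta_nat: np.ndarray) -> float:
        B, Psi = _matrices(spec, theta_nat)
        A = np.linalg.solve(eye - B, eye)
        sigma = A @ Psi @ A.T
        s, logdet = np.linalg.slogdet(sigma)
        if s <= 0 or not np.isfinite(logdet):
            return np.inf
        return logdet + float(np.trace(S @ np.linalg.inv(sigma))) - logdet_S - p

    def fisher_polish(theta: np.ndarray, max_steps: int = 100):
        """Fisher scoring on the natural scale: Newton steps with the
        expected Hessian of F (positive definite at regular points), with
        step halving; quadratic convergence near the optimum."""
        F_cur = f_only(theta)
        if not np.isfinite(F_cur):
            return theta, 0
        steps = 0
        for _ in range(max_steps):
            B, Psi = _matrices(spec, theta)
            A = np.linalg.solve(eye - B, eye)
            sigma = A @ Psi @ A.T
            sigma_inv = np.linalg.inv(sigma)
            G = sigma_inv - sigma_inv @ S @ sigma_inv
            deltas = _delta_matrices(spec, A, sigma, kinds, rows, cols)
            g_nat = np.array([float(np.sum(G * d)) for d in deltas])
            if np.max(np.abs(g_nat)) < 1e-10:
                break
            Pv = np.stack([(sigma_inv @ d).ravel() for d in deltas])
            Pw = np.stack([(sigma_inv @ d).T.ravel() for d in deltas])
            Hexp = Pv @ Pw.T
            try:
                step = np.linalg.solve(Hexp + 1e-12 * np.eye(len(g_nat)), -g_nat)
            except np.linalg.LinAlgError:
                break
            improved = False
            for _half in range(30):
                cand = theta + step
                if np.all(cand[kinds == 1] > 0):
                    F_new = f_only(cand)
                    if F_new <= F_cur - 1e-16 or (
                        np.isfinite(F_new) and F_new <= F_cur + 1e-15
                    ):
                        theta, F_cur = cand, F_new
                        improved = True
                        break
                step *= 0.5
            steps += 1
            if not improved:
                break
        return theta, steps

    theta0 = _start_values(spec, S)
    theta, n_iter = fisher_polish(theta0)
    x = _pack(theta, kinds)
    _, g = f_and_grad(x)
    if np.max(np.abs(g)) > 1e-5:
        # fall back to quasi-Newton from the best point so far, then
        # re-polish; keep the fallback only if it actually improved F
        res = optimize.minimize(
            f_and_grad,
            x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        n_iter += int(res.nit)
        theta2, extra = fisher_polish(_unpack(res.x, kinds))
        n_iter += extra
        if f_only(theta2) < f_only(theta):
            theta = theta2
        x = _pack(theta, kinds)
        _, g = f_and_grad(x)
    grad_norm = float(np.max(np.abs(g)))
    converged = grad_norm < 1e-6

    theta = _unpack(x, kinds)
    F_min, _ = f_and_grad(x)
    B, Psi = _matrices(spec, theta)
    A = np.linalg.solve(eye - B, eye)
    sigma = A @ Psi @ A.T
    T = max((n - 1) * F_min, 0.0)
    p_value = float(stats.chi2.sf(T, df)) if df > 0 else 1.0

    # write estimates back into the spec's parameter objects
    params = spec.parameters()
    it = iter(theta)
    estimates: dict[str, float] = {}
    for prm in params:
        if prm.free:
            prm.value = float(next(it))
        if prm.kind == "cov":
            spec._covs[(prm.lhs, prm.rhs)] = prm
        estimates[prm.label] = prm.value

    se, vcov, free_labels = _standard_errors(spec, sigma, A, n, kinds, rows, cols)
    fitted = FittedModel(
        spec=spec,
        n=n,
        S=S,
        B=B,
        Psi=Psi,
        sigma=sigma,
        estimates={prm.label: prm.value for prm in params},
        se=se,
        chi2=T,
        df=df,
        p_value=p_value,
        converged=converged,
        grad_norm=grad_norm,
        n_iter=n_iter,
        free_labels=free_labels,
        vcov=vcov,
    )
    if compute_indices:
        fitted.indices = fit_indices(T, df, n, S, sigma)
    return fitted


def _delta_matrices(spec: ModelSpec, A: np.ndarray, sigma: np.ndarray, kinds, rows, cols):
    """dSigma/dtheta_k (natural scale) for each free parameter."""
    out = []
    for kd, i, j in zip(kinds, rows, cols):
        if kd == 0:  # path i <- j
            E = np.zeros_like(sigma)
            E[i, j] = 1.0
            dA = A @ E
            dS = dA @ sigma  # A E_ij Sigma
            out.append(dS + dS.T)
        else:
            E = np.zeros_like(sigma)
            E[i, j] = 1.0
            if i != j:
                E[j, i] = 1.0
            out.append(A @ E @ A.T)
    return out


def _standard_errors(spec, sigma, A, n, kinds, rows, cols):
    """Expected-information SEs (and full vcov) on the natural scale."""
    sigma_inv = np.linalg.inv(sigma)
    deltas = _delta_matrices(spec, A, sigma, kinds, rows, cols)
    q = len(deltas)
    info = np.empty((q, q))
    pre = [sigma_inv @ d for d in deltas]
    for a in range(q):
        for b in range(a, q):
            info[a, b] = info[b, a] = 0.5 * (n - 1) * float(np.sum(pre[a] * pre[b].T))
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
    except np.linalg.LinAlgError:
        cov = np.full((q, q), np.nan)
        diag = np.full(q, np.nan)
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.where(diag > 0, diag, np.nan))
    labels = [prm.label for prm in spec.parameters() if prm.free]
    se = dict(zip(labels, ses))
    for prm in spec.parameters():
        if not prm.free:
            se[prm.label] = 0.0
    return se, cov, labels


# ---------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------


def _baseline_chi2(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence baseline: all covariances fixed to 0, variances free.

    The MLE is Sigma0 = diag(S), so the minimised discrepancy has the
    closed form ln|diag(S)| - ln|S|.
    """
    p = S.shape[0]
    _, logdet_S = np.linalg.slogdet(S)
    F0 = float(np.sum(np.log(np.diag(S)))) - logdet_S
    return max((n - 1) * F0, 0.0), p * (p + 1) // 2 - p


def fit_indices(T: float, df: int, n: int, S: np.ndarray, sigma: np.ndarray) -> FitIndices:
    """CFI, RMSEA (point + 90% CI by noncentral-chi2 inversion), SRMR."""
    T0, df0 = _baseline_chi2(S, n)
    num = max(T - df, 0.0)
    denom = max(T0 - df0, T - df, 0.0)
    cfi = 1.0 - (num / denom if denom > 0 else 0.0)
    if df > 0:
        rmsea = math.sqrt(num / (df * (n - 1)))
        ci = _rmsea_ci(T, df, n)
    else:
        rmsea, ci = 0.0, (0.0, 0.0)
    d = np.sqrt(np.diag(S))
    dh = np.sqrt(np.diag(sigma))
    r = S / np.outer(d, d) - sigma / np.outer(dh, dh)
    tril = np.tril_indices_from(r)
    srmr = float(np.sqrt(np.mean(r[tril] ** 2)))
    return FitIndices(
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        rmsea=rmsea,
        rmsea_ci=ci,
        srmr=srmr,
        chi2_baseline=T0,
        df_baseline=df0,
    )


def _rmsea_ci(T: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """90% CI by inverting the noncentral chi-square distribution."""
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2  # 0.95, 0.05

    def bound(target: float) -> float:
        if stats.ncx2.cdf(T, df, 0.0) < target:
            return 0.0
        hi = max(T, 1.0)
        while stats.ncx2.cdf(T, df, hi) > target:
            hi *= 2
            if hi > 1e8:
                return math.nan
        lam = optimize.brentq(lambda l: stats.ncx2.cdf(T, df, l) - target, 0.0, hi)
        return math.sqrt(lam / (df * (n - 1)))

    return (bound(lo_q), bound(hi_q))


# ---------------------------------------------------------------------
# Satorra-Bentler scaling
# ---------------------------------------------------------------------


def _duplication(p: int) -> np.ndarray:
    """Duplication matrix D with vec(M) = D vech(M) for symmetric M."""
    rows_t, cols_t = np.tril_indices(p)
    ps = len(rows_t)
    D = np.zeros((p * p, ps))
    for k, (i, j) in enumerate(zip(rows_t, cols_t)):
        D[i * p + j, k] = 1.0
        D[j * p + i, k] = 1.0
    return D


def _vech(M: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(M.shape[0])
    return M[i, j]


def satorra_bentler_scale(data, fitted: FittedModel) -> tuple[float, float]:
    """Satorra-Bentler scaled chi-square and scaling factor c.

    ``data`` is the raw n x p matrix (or DataFrame) aligned to the
    model's variables.  c = tr(U Gamma) / df with Gamma the empirical
    fourth-moment asymptotic covariance of vech(S) and U the
    normal-theory residual weight matrix; under multivariate normality
    c -> 1.  Requires df > 0.
    """
    spec = fitted.spec
    if fitted.df == 0:
        raise ValueError("Satorra-Bentler scaling is undefined for df = 0")
    if isinstance(data, pd.DataFrame):
        data = data[spec.variables].to_numpy()
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if p != len(spec.variables):
        raise ValueError("data columns must match the model variables")
    if n < 10 * p:
        import warnings

        warnings.warn(
            "sample may be too small for stable fourth-moment estimates",
            stacklevel=2,
        )
    Xc = X - X.mean(axis=0)
    d = np.stack([_vech(np.outer(x, x)) for x in Xc])
    gamma = np.cov(d, rowvar=False, ddof=1)

    sigma_inv = np.linalg.inv(fitted.sigma)
    D = _duplication(p)
    V = 0.5 * D.T @ np.kron(sigma_inv, sigma_inv) @ D
    kinds, rows, cols = _free_layout(spec)
    eye = np.eye(p)
    A = np.linalg.solve(eye - fitted.B, eye)
    deltas = _delta_matrices(spec, A, fitted.sigma, kinds, rows, cols)
    Delta = np.stack([_vech(dS) for dS in deltas], axis=1)
    VD = V @ Delta
    U = V - VD @ np.linalg.solve(Delta.T @ VD, VD.T)
    c = float(np.trace(U @ gamma)) / fitted.df
    scaled = fitted.chi2 / c
    if fitted.indices is not None:
        fitted.indices = FitIndices(
            **{
                **fitted.indices.__dict__,
                "scaled_chi2": scaled,
                "scaling_factor": c,
            }
        )
    return scaled, c
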