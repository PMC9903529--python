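# Methods

## Compositional geometry

The unit of analysis is the 5-part daily time-use composition
(vigorous, moderate and light physical activity, sedentary behaviour,
sleep) in minutes per day.  Compositions are equivalence classes under
positive scaling; `closure` fixes the representative at a 1440-min day.
Published descriptive centres that sum to 1441 min are treated as
rounding artefacts and re-closed to 1440.

The ILR basis is the pivot sequential binary partition
V | M,L,SB,Sl → M | L,SB,Sl → L | SB,Sl → SB | Sl, implemented as an
orthonormal 5×4 contrast matrix in clr space.  The part order is fixed
and the basis is exactly this pivot — not a generic Helmert rotation —
so individual coordinates are interpretable (ilr1 = vigorous activity
against the geometric mean of everything else) and coefficients can be
compared coordinate by coordinate.  Orthonormality gives the isometry
with the Aitchison distance that the tests assert to 1e−10; the
inverse transform subtracts the clr maximum before exponentiating so
extreme coordinates cannot overflow.

Natural logarithms are used throughout.  Observed zero parts (possible
for vigorous activity at daily resolution) are handled by
multiplicative replacement with a configurable floor of 1 min/day —
the smallest meaningful unit at daily resolution — before closure.

Compositional descriptives are the geometric-mean composition (per-part
geometric means, re-closed) and the variation matrix of pairwise
log-ratio variances (sample variance, ddof = 1); small entries flag
proportionally co-varying behaviours.  For ternary display the five
parts are amalgamated to three groups (default
sleep | sedentary | active = VPA+MPA+LPA; the grouping is configurable
because the three-way split used in any given figure is a display
choice, not part of the model).

The proportional reallocation operator moves δ minutes into a target
behaviour and rescales the remaining four by a common factor so the day
total is preserved.  When the target is vigorous activity this
perturbs only ilr1 (the common factor cancels inside ilr2–ilr4), which
is what makes the reallocation predictor a one-coordinate exercise.
Note that the ilr1 increment depends on the base composition only
through the target behaviour's minutes (given the fixed day length),
so bases with equal VPA but different splits of the rest give
identical curves — the tests assert this sharper form of the
invariance.

## Accelerometer stage

Inputs are ENMO-style acceleration magnitudes (milli-g) at a fixed
epoch length (default 5 s) with per-epoch wear and sleep flags supplied
upstream; non-wear/sleep detection algorithms are out of scope here.
Awake wear epochs are classified by the child intensity cut-points
SB < 35 mg, LPA 35–199, MPA 200–699, VPA ≥ 700.  The printed integer
band edges are implemented as half-open real intervals [35, 200),
[200, 700) so arbitrary magnitudes classify unambiguously.  Days are
midnight-to-midnight; a day is valid with ≥ 16 h of wear and a
participant with ≥ 1 valid day (≥ 3 in the sensitivity mode).  Non-wear
epochs contribute neither behaviour minutes nor wear time and are not
imputed — the later closure normalises relative time use.  Behaviour
minutes are averaged over valid days first and closed afterwards
(the reverse order would weight days by their wear coverage).

## Path-model estimator

Models are recursive observed-variable systems x = Bx + e,
Cov(e) = Ψ, with implied covariance Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ; no mean
structure (reporting is standardized), no latent factors, listwise
complete input.  The ML discrepancy
F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimised with analytic
gradients: for free Ψ entries the gradient is read off A᷈ᵀGA with
G = Σ⁻¹(Σ−S)Σ⁻¹ and A = (I−B)⁻¹, and for free B entries off
2AᵀGΣ, so a full gradient costs a handful of p×p products.

Optimisation is Fisher scoring from equation-wise least-squares
starting values: Newton steps with the expected Hessian
tr(Σ⁻¹ ∂Σⱼ Σ⁻¹ ∂Σₖ) (positive definite at regular points) and step
halving, targeting a gradient ∞-norm of 1e−10; if scoring stalls above
1e−5 a quasi-Newton (L-BFGS-B) pass on the log-variance
parameterisation is run and kept only if it lowers F.  Variances are
kept positive by the log parameterisation inside the quasi-Newton leg
and by the positivity line-search constraint inside scoring.  In
double precision the attainable gradient floor scales with F itself,
so `converged` is declared below an ∞-norm of 1e−6; typical fits end
around 1e−10.

χ² is T = (n−1)F at the minimum; df = p(p+1)/2 minus the number of
free parameters.  Standard errors come from the inverse expected
information ((n−1)/2)·tr(Σ⁻¹∂Σⱼ Σ⁻¹∂Σₖ) on the natural scale, and the
full parameter covariance is retained for delta-method composites.
Standardized coefficients rescale by implied SDs and are invariant to
linear rescaling of observed variables.  p-values are central-χ² upper
tails for T and two-sided Wald for parameters.

Fit indices follow the usual definitions: CFI against the independence
baseline (all covariances fixed at zero; its ML minimum has the closed
form ln|diag S| − ln|S|), RMSEA = √(max(T−df,0)/(df(n−1))) with a 90 %
interval from inverting the noncentral-χ² cdf, and SRMR as the RMS of
standardized residual moments over the lower triangle including the
diagonal.  The Satorra–Bentler scaling factor is c = tr(UΓ̂)/df with
Γ̂ the empirical fourth-moment covariance of vech(S) and
U = V − VΔ(ΔᵀVΔ)⁻¹ΔᵀV, V = ½Dᵀ(Σ̂⁻¹⊗Σ̂⁻¹)D; it is computed whenever
raw data are available (df > 0) and skipped, with the plain ML T still
reported, for covariance-only input.  Under multivariate normality
c → 1; the tests check this and the elliptical heavy-tail direction
(multivariate t(10), where common-kurtosis theory gives c ≈ 1.33).

## The cross-lagged and mediation models

The two-wave cross-lagged specification frees: same-coordinate ILR
autoregression (4 paths); every baseline ILR → every follow-up outcome,
every baseline outcome → every follow-up ILR and outcome; covariate
paths (sex, both ages, maternal education, group allocation, optionally
energy intake at both waves) to all follow-up variables; saturated
covariances within the baseline + covariate block; and all follow-up
residual covariances.  Lags between *different* ILR coordinates are
omitted; those 12 omitted paths are exactly the model's 12 degrees of
freedom, for both the 2-outcome body-composition set and the 3-outcome
fitness set.  This reading was adopted because it yields the same df
for both configurations; a `lag_structure="saturated"` switch frees
the cross-coordinate lags (df drops to 0) for sensitivity.  Motor
fitness (4×10-m shuttle seconds) is sign-flipped in the model frame so
higher = better for every outcome; the flip is recorded in the column
derivation.

Mediation uses the two-equation recursive model M ~ X + Z and
Y ~ M + X + Z, where X is a baseline ILR coordinate, M its follow-up
value, Y a follow-up outcome, and Z the covariates plus the remaining
baseline ILR coordinates (so the full 24-h composition is held).
Follow-up values of the other coordinates are co-mediators and are
excluded from Z by default, with a flag to include them.  The model is
just-identified, so path estimates equal equation-wise least squares —
asserted against statsmodels OLS in the tests.  indirect = a·b with
delta-method variance b²σ²ₐ + a²σ²ᵦ + 2abσₐᵦ; total = c′ + a·b exactly;
an optional seeded percentile bootstrap refits the same model on
resampled rows.  Effects are reported standardized (z-scored refit)
and in raw units; the raw coefficients drive the reallocation
predictor, whose default variant is the total effect (indirect-only is
produced alongside) and whose default base composition is the cohort
geometric mean.  A condition-number guard (> 1e8) rejects collinear
adjustment sets.

## Synthetic cohort generator

The generator emulates a two-wave cohort of Swedish children measured
at ~4.5 and ~9.6 years.  Wave-1 ILR coordinates and standardized
outcomes are jointly multivariate normal; wave-2 variables follow the
linear cross-lagged equations with configurable standardized
coefficients; compositions are recovered through the inverse ILR map
(a logistic-normal model on the simplex).  Because every structural
variable is budgeted to unit marginal variance (residual variance =
1 − explained), injected standardized coefficients are the generating
standardized effects, so published β values can be dialled in
directly.

Defaults, fixed once as the study conditions:

* composition centres 10/55/346/512/518 min (wave 1) and
  13/54/294/537/543 min (wave 2), the cohort geometric means;
* ILR tracking 0.19/0.21/0.08/0.17 and outcome tracking 0.3–0.5;
  cross-lags FMI→ilr1 = −0.22, FMI→ilr3 = −0.19, aerobic→ilr3 = −0.22;
  all behaviour→outcome lags null (none was detected in the source
  analyses);
* concurrent wave-2 residual correlations (e.g. ilr1–FMI −0.25) and a
  wave-1 correlation matrix with ilr1–FMI −0.30, ilr4–FMI 0.23, and
  modest within-block correlations;
* covariates: sex Bernoulli(0.5), ages N(4.5, 0.1²)/N(9.6, 0.1²),
  maternal university education Bernoulli(0.708), group Bernoulli(0.5);
* outcome scales: FMI 4.1±0.9 → 3.6±1.9, FFMI 11.6±1.0 → 13.5±1.1
  kg/m², aerobic 15.8±1.4 → 17.1±2.5 laps; ILR coordinate SDs
  (0.45, 0.30, 0.20, 0.16) and motor/strength scales are the package's
  own choices, documented here, because the available descriptive
  table is not internally consistent for those cells;
* exclusion flags drawn as disjoint sets of 9/12/9 on a 231-child
  roster (an overlapping mode exists for testing the cascade logic).

The generator reproduces the structure the models assume — linearity,
joint normality on the ILR scale, missingness independent of the
values.  It does not emulate diurnal activity patterns, bout
structure, device noise, floor effects in vigorous activity, or
informative dropout; passing recovery tests therefore demonstrate the
correctness and calibration of the estimator under the model class,
not robustness to real-data violations (the Satorra–Bentler machinery
addresses non-normality when it arises).

Epoch traces for the accelerometer round trip allocate per-behaviour
epoch counts by largest remainder (exact at 5-s resolution) and draw
magnitudes uniformly inside each behaviour's intensity band, with
sleep epochs flagged and given sub-sedentary magnitudes.

## Simulation scale and reproducibility

Calibration checks use 100 simulated cohorts of n = 200 (cross-lag
recovery within ±0.02 of the injected −0.22 and 90–99 % CI coverage;
lagged cross-path type-I error ≈ 5 %) and 100–150 replicates for the
mediation recovery; these sizes put the Monte-Carlo standard error of
a coverage estimate near 2 % while keeping a full run to a couple of
minutes.  All randomness flows from explicit seeds
(`numpy.random.default_rng`); the pipeline writes a manifest with the
seed and a configuration hash, and identical seeds give byte-identical
reports.

## Known limitations

Observed-variable models only (no latent factors, no FIML for missing
data, no categorical estimators, no multi-group or >2-wave designs).
The RMSEA confidence interval follows the standard noncentral-χ²
inversion.  Mediation with mediator and outcome measured at the same
wave is an ordering assumption, not a temporal identification; the
reallocation curves inherit the causal caveats of the fitted
coefficients.  Weight-status classification requires a caller-supplied
age/sex BMI reference table; none is bundled.
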