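"""Fit the cross-lagged panel model on a synthetic two-wave cohort.

Generates 231 children measured at ~4.5 and ~9.6 years, applies the
9/12/9 exclusion cascade down to 201, and fits the body-composition
cross-lagged model: ILR tracking paths, behaviour/outcome cross-lags,
covariate adjustment, and saturated concurrent covariances (df = 12).
"""

from movecoda import GeneratorParams, apply_exclusions, generate_cohort, inject_missingness
from movecoda.clpm import ClpmConfig, build_model_frame, run_clpm

cohort = inject_missingness(generate_cohort(GeneratorParams(n=231, seed=42)), seed=42)
analytical, report = apply_exclusions(cohort)
print(report)

frame = build_model_frame(analytical)
result = run_clpm(frame, ClpmConfig(outcome_set="bodycomp"))
f = result.fitted
fi = f.indices
print(f"\nchi2 = {f.chi2:.2f}, df = {f.df}, p = {f.p_value:.3f}")
print(f"CFI = {fi.cfi:.3f}, RMSEA = {fi.rmsea:.3f}, SRMR = {fi.srmr:.3f}, "
      f"Satorra-Bentler scaling = {fi.scaling_factor:.3f}")
# A well-fitting model: chi2 near its df, CFI ~ 1, RMSEA/SRMR near 0.

print("\nsignificant lagged and concurrent paths (p < 0.05):")
print(result.significant().to_string(index=False))
# 'beta' is the standardized coefficient; the generator injects a
# standardized FMI(4y) -> ILR1(9y) cross-lag of -0.22 and ILR tracking
# around 0.17-0.21, which the fit should recover within sampling error.
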