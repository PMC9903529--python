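# movecoda

Compositional analysis of 24-hour movement behaviours for two-wave
child cohorts: isometric log-ratio (ILR) coordinates, cross-lagged
panel models, compositional mediation, and a minutes-per-day
reallocation predictor.

## The problem

A child's day is fully partitioned into vigorous physical activity
(VPA), moderate physical activity (MPA), light physical activity
(LPA), sedentary behaviour (SB) and sleep.  Because these five parts
must sum to 1440 min, they carry only *relative* information: raising
one behaviour necessarily lowers others, and treating the minutes as
ordinary covariates invites spurious multicollinearity.  `movecoda`
works in the Aitchison simplex instead.  A composition
**x** = (V, M, L, SB, Sl) is mapped to four pivot ILR coordinates

```
ilr1 = sqrt(4/5) ln[ V / (M·L·SB·Sl)^(1/4) ]
ilr2 = sqrt(3/4) ln[ M / (L·SB·Sl)^(1/3) ]
ilr3 = sqrt(2/3) ln[ L / (SB·Sl)^(1/2) ]
ilr4 = sqrt(1/2) ln[ SB / Sl ]
```

so that ilr1 captures the effect of more vigorous activity at the
proportional expense of everything else, and so on down the partition.

On top of this geometry the package estimates, by normal-theory
maximum likelihood on the covariance structure
Σ(θ) = (I−B)⁻¹ Ψ (I−B)⁻ᵀ:

* **cross-lagged panel models** over two waves (ages ~4.5 and ~9.6 y)
  linking the four ILR coordinates to body-composition outcomes (fat
  mass index, fat-free mass index) or physical-fitness outcomes
  (aerobic, motor, muscular), with same-coordinate autoregression
  ("tracking"), free behaviour↔outcome cross-lags, covariate
  adjustment (sex, ages, maternal education, group allocation,
  optionally energy intake) and saturated concurrent covariances —
  df = 12 for both outcome sets;
* **mediation**: baseline ILR coordinate → its follow-up value →
  follow-up outcome, with delta-method and bootstrap inference for the
  indirect effect a·b, adjusted for the rest of the composition;
* **reallocation curves**: the mediation coefficients re-expressed as
  the predicted outcome change when δ min/day move into VPA
  proportionally from the remaining behaviours.

Fit statistics include the ML χ², CFI, RMSEA with a 90 % noncentral-χ²
confidence interval, SRMR, and the Satorra–Bentler scaled χ² computed
from empirical fourth moments.

Upstream of the models, the package classifies epoch-level
acceleration magnitudes (ENMO, milli-g, 5-s epochs) into behaviours
with the child cut-points (SB < 35, LPA 35–199, MPA 200–699,
VPA ≥ 700 mg), applies the 16-h wear / ≥1-valid-day rule, derives
participant phenotypes (BMI, weight status, relative grip, muscular
z-score composite), and runs the 231 → 201 exclusion cascade.  A
seeded synthetic-cohort generator emulates the whole data structure so
every stage is testable without access to individual-level data.

## Worked example

```python
from movecoda import GeneratorParams, apply_exclusions, generate_cohort, inject_missingness
from movecoda.clpm import ClpmConfig, build_model_frame, run_clpm

cohort = inject_missingness(generate_cohort(GeneratorParams(n=231, seed=42)), seed=42)
analytical, report = apply_exclusions(cohort)
print(report)
result = run_clpm(build_model_frame(analytical), ClpmConfig("bodycomp"))
```

prints

```
roster: 231
  - insufficient_accelerometer: removed 9 -> 222
  - incomplete_body_composition: removed 12 -> 210
  - incomplete_physical_fitness: removed 9 -> 201
analytical sample: 201

chi2 = 5.37, df = 12, p = 0.944
CFI = 1.000, RMSEA = 0.000, SRMR = 0.012, Satorra-Bentler scaling = 0.970
```

The cascade removes exactly the 9/12/9 flagged children, and the
model fits well (χ² below its 12 df, CFI ≈ 1) because the generator
draws from the model's own structure.  Among the significant paths,
`ilr1_w2 ~ ilr1_w1` (standardized β ≈ 0.17) is the tracking of
vigorous activity and `ilr1_w2 ~ fmi_w1` (β ≈ −0.24) the cross-lag
from early fat mass to later vigorous activity — both near the
standardized effects the generator injects (0.19 and −0.22).

The mediation and reallocation step (`examples/04`) continues:

```
mediation ilr1_w1 -> ilr1_w2 -> fmi_w2 (n = 201)
  a (X->M):      +0.2860 (se 0.0717, p 0.0001)
  b (M->Y):      -1.3037 (se 0.2531, p 0.0000)
  indirect a*b:  -0.3729 (se 0.1182, p 0.0016)
  ...
  +  10 min/day VPA -> predicted FMI change -0.527 kg/m^2
```

i.e. vigorous activity tracks from 4 to 9 years (a > 0), more of it at
9 years goes with lower fat mass index (b < 0), and shifting 10
min/day into VPA from the other behaviours predicts about half a
kg/m² lower FMI under the fitted total effect.

The `examples/` directory holds one short script per capability, and
`movecoda --help` exposes the same stages as a command line
(`simulate`, `process`, `fit-clpm`, `fit-mediation`, `reallocate`,
`all`).

## Layout

```
src/movecoda/
  coda.py       compositional geometry (closure, ILR, descriptives, reallocation)
  accel.py      epoch classification, wear-time validity, person compositions
  cohort.py     phenotype derivations and the exclusion cascade
  pathmodel.py  ML covariance-structure estimator, fit indices, robust scaling
  clpm.py       cross-lagged / mediation specs and the reallocation predictor
  synthgen.py   seeded synthetic-cohort and epoch-trace generator
  pipeline.py   end-to-end orchestration with manifests
  cli.py        thin command-line wrapper
docs/methods.md the model, its assumptions, and all numerical choices
```
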