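# spiroref

Spirometric reference equations, GOLD severity staging, and between-equation
agreement statistics for adult cohorts.

## The problem

Whether a spirometry result is "normal" depends on a reference equation: the
predicted FEV1 (forced expiratory volume in 1 s), FVC (forced vital capacity)
and FEV1/FVC ratio for a person of a given sex, age and height. Europe has
long used the linear ECSC-1993 equations; GLI-2012 replaced them with a
multi-ethnic LMS model; and many groups derive local equations from healthy
volunteers. Because GOLD stages COPD severity by *percent-predicted* FEV1
(stage 1 ≥ 80%, 2 = 50–79%, 3 = 30–49%, 4 < 30%, with obstruction defined by
a measured FEV1/FVC below 70%), the choice of equation set can in principle
re-stage a patient. This package implements one locally derived equation set
alongside ECSC-1993 and a GLI-2012-style LMS model, stages cohorts under
each, and quantifies how much the choice actually matters.

It is a library for epidemiologists and respiratory researchers: the API and
the short scripts in `examples/` are the interface (no CLI).

## The models

**Local equations** (healthy adults 18–89, fitted by OLS, sex-stratified):
age enters piecewise-linearly with a knot at 25 years (basis `min(A,25)`,
`max(A−25,0)`), height linearly and, where significant, quadratically; FVC is
modelled on the natural-log scale with a negative weight term; the FEV1/FVC
ratio depends on age alone (linear for men, quadratic for women). Example
(men, age ≥ 25):

    FEV1 = −25.144 + 0.296·H − 0.000728·H² − 0.0288·(A − 25)   [L; H in cm]

**ECSC-1993**: linear in height (m) and age, with ages below 25 clamped to 25.

**GLI-style LMS**: median `M = exp(a0 + a1·ln H + a2·ln A + spline(A))`,
coefficient of variation `S`, skewness power `L`; z-score
`((y/M)^L − 1)/(L·S)` and LLN at the 5th centile. The packaged lookup table
is a clearly-labelled *synthetic stand-in* with the genuine functional form
(the official GLI coefficient tables are not redistributable here); pass your
own table to `gli_predict` for real GLI numbers.

**Agreement battery**: exact percent agreement and Cohen's kappa (unweighted,
linear, quadratic weights) on 4×4 stage cross-tabulations, plus Lin's
concordance correlation coefficient
`ρc = 2·cov(x,y) / (var x + var y + (x̄ − ȳ)²)` for continuous indices.
Linear weights are the default because they reproduce the published agreement
coefficients from the published cross-tabulations.

A seeded synthetic-cohort generator (healthy and COPD) makes the whole
pipeline testable without any external data.

## Worked example

```bash
python examples/agreement_from_published_tables.py
```

prints, for the packaged published staging cross-tabulations of 124 COPD
patients:

```
local_vs_ecsc: n=124
  exact agreement : 116/124 = 93.5%
  kappa unweighted: 0.909
  kappa linear    : 0.936   <- published convention
  kappa quadratic : 0.962
...
ecsc_vs_gli: n=124
  exact agreement : 107/124 = 86.3%
  kappa linear    : 0.862   <- published convention
```

i.e. staging under the local equations and ECSC agrees exactly for 116 of
124 patients, and the chance-corrected linear-weighted agreement is 0.936 —
"almost perfect" on the usual kappa scale. The other examples predict and
stage a single subject (`predict_and_stage.py`), refit the six equations on
a simulated cohort (`refit_equations.py`), and run the full
predict→stage→agree pipeline end to end (`full_pipeline.py`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged ratio equations and the cohort age moments,
the mean study-predicted FEV1/FVC ratio of healthy and COPD men (the
equation is linear in age, so the mean prediction equals the prediction at
the mean age), its SD (|age slope| × age SD), and the healthy women's mean
from the quadratic model via E[A²] = mean² + SD², writing one JSON object
keyed by target id.

## Layout

- `src/spiroref/` — `cohort` (types + I/O), `local` / `reference`
  (equation sets), `fitting` (piecewise OLS refits), `agreement`
  (staging + statistics), `simulate` (synthetic cohorts), `pipeline`
  (end-to-end runs), `datasets` (packaged tables).
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
- `examples/` — one short narrative script per capability.
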