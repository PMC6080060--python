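# Methods

## Prediction equations

### Local equations

Six sex-specific OLS models fitted on healthy adults (18–89 y):

| outcome | scale | covariates (men) | covariates (women) |
|---|---|---|---|
| FEV1 | litres | age (piecewise), H, H² | age (piecewise), H |
| FVC | ln litres | age (piecewise), H, H², W | age (piecewise), H, H², W |
| FEV1/FVC | percent | A | A, A² |

Age is piecewise linear with a fixed knot at 25 years, reflecting the rise of
lung function to a plateau in the mid-20s and its decline thereafter. The
equations are published as two display branches (age < 25, age ≥ 25); branch
assignment here is `age < 25 → young`, the knot itself belonging to the old
branch.

Two coefficient-table variants ship:

- **corrected** (default): the young-branch height-quadratic term of the male
  ln(FVC) model is −0.00041·H², not the printed +0.00041·H². The positive
  sign gives ln FVC ≈ 26 (≈ 10¹¹ litres); the negative sign is the only
  reading consistent with finite lung volumes, with the old branch, and with
  the female model's structure.
- **as_printed**: the source text verbatim, for audit.

Known blemishes preserved deliberately: the male ln(FVC) branches are
discontinuous by ≈ 0.066 at the knot (both printed intercepts kept; no
smoothing), and the printed male FVC model evaluates ≈ 10% below the
published cohort-mean predicted FVC — neither is repaired because fidelity to
the published coefficients takes precedence, and no cohort-level FVC quantity
is treated as a numeric target.

The continuous-basis form used for simulation and refitting
(`{1, min(A,25), max(A−25,0), H, H², W}`) anchors the age ≥ 25 branch exactly
and keeps the printed young slope; where the printed branches are continuous
this reproduces the young branch to the 0.001 rounding of the printed
intercepts (0.066 for male ln FVC, per the gap above).

### ECSC-1993

Linear in height (metres) and age; ages 18–25 are clamped to 25 per the
source's young-adult convention. The transcribed coefficients reproduce the
published cohort-mean ECSC predictions at the cohort's mean age/height to
printed precision (checked in the test suite).

### GLI-style LMS

`M = exp(a0 + a1 ln H + a2 ln A + Mspline(A))`,
`S = exp(p0 + p1 ln A + Sspline(A))`, Box-Cox power `L`;
`z = ((y/M)^L − 1)/(L·S)`, `LLN = M(1 + L·S·z₀.₀₅)^{1/L}` with z₀.₀₅ =
−1.645. Spline values (and L) are linearly interpolated on a 1-year age grid
18–95; no extrapolation. The ratio has its own LMS lookup rather than being
the quotient of predicted volumes, matching GLI practice.

**The packaged lookup is synthetic** (`gli_lookup_synthetic.tsv`, version
string `synthetic-1.0`, logged in every pipeline run header): the official
GLI-2012 coefficient tables could not be redistributed in this build, so a
stand-in with the genuine functional form was constructed once — median
curves anchored to the local equations at sex-typical reference heights
(176/163 cm), scaled by the rough GLI-vs-local offsets seen in published
summary tables (+4% FEV1, +7% FVC, −3% ratio), height exponents ≈ 2.1 for
volumes, CVs rising from ~11% to ~15% (volumes) and ~5% to ~8% (ratio) over
adulthood. Quantities that depend on the *real* GLI table (published GLI
cohort means, Lin's concordance against GLI) are therefore pipeline outputs,
never numeric targets. Users with the official table can pass it directly.

### Cross-source envelope

The claim that the three sets are "nearly identical" is asserted as: over a
typical-population grid (ages 20–80, heights within ±1.5 SD of the sex
means), every pairwise ratio of predictions lies in [0.7, 1.3]. At more
extreme corners (85+ years with heights beyond ±1.5 SD) the linear ECSC form
and the power-law LMS form genuinely diverge past that factor; the grid is
deliberately the region where the source cohorts have data.

## Staging and agreement

GOLD bands on unrounded percent-predicted FEV1: ≥ 80, [50, 80), [30, 50),
< 30. The optional obstruction gate uses the fixed-ratio rule (measured
FEV1/FVC < 70%), not source-specific LLNs; it defaults off because the
cohorts being staged are already diagnosed COPD.

Weighted kappa uses `w_ij = 1 − |i−j|/(k−1)` (linear) by default. The
weighting was frozen by a decisive check, not convention: linear weights
reproduce all three published coefficients (0.936, 0.895, 0.862) from the
published count tables; unweighted gives 0.909/0.852/0.806 and quadratic
0.962/0.937/0.917. Degenerate marginals yield NaN with a warning rather than
an exception. Lin's ρc uses 1/n moment estimators per the original
definition (`estimator="sample"` selects 1/(n−1)); |ρc| ≤ |r| always holds
since the bias-correction factor is ≤ 1. Reported average differences follow
the predicted-minus-measured convention.

One published-rounding note: the source prints "93.6% (116/124)", but
116/124 = 93.55% → 93.5%; the count 116 is authoritative. Likewise a text
figure "110/124" conflicts with its table's diagonal of 111; the table is
used.

## Synthetic cohorts

**Healthy** (defaults = the study's Table of demographics, n = 500, 239 men):
sex-stratified truncated-normal age/height/weight (age ∈ [18, 89], height
∈ [140, 205] cm, weight ∈ [40, 160] kg), drawn independently per subject —
the source gives only marginals, so no age–height correlation is simulated;
this deflates refit R² relative to real data but leaves coefficient recovery
unbiased. Measured FEV1 = local equation + N(0, 0.38/0.28 L); measured
ln FVC = local ln-model + N(0, 0.12/0.13); the two residuals of one subject
are drawn with correlation 0.8 (same maneuver, same lungs — marginal SDs
unchanged). The noise is *not* truncated at FEV1 = FVC: refits then see
exactly Gaussian residuals, at the price of a small tail (~5–10% of men) of
physically incoherent spirograms, which the `Spirogram` type tolerates with
a warning. File readers still reject rows with FEV1 > 1.02·FVC, so noisy
synthetic cohorts are for in-memory pipelines, not round-trip archives.

**COPD** (defaults: n = 124, 84 men, stage mix 17:44:42:21/124): a target
stage per subject, percent-predicted FEV1 uniform in that stage's band
(stage 1 capped at 95%, stage 4 floored at 15%), measured FEV1 = band
fraction × local predicted FEV1, measured ratio uniform in [40, 69]% (below
the 70% gate by construction, approximating the published COPD measured
ratio 57.9 ± 10.6), FVC derived from the pair. Staging such a cohort with
the local source inverts the construction exactly. Ages span [24, 91] as in
the source COPD cohort; the top 2 years extrapolate the equations slightly
(validated to 95 internally).

What a green test does **not** establish: recovery of the published R²
values (they depend on the real covariate correlations), realism of the GLI
stand-in, or any property of the real cohorts' individual-level data.

## Fitting

`fit_ols` delegates to statsmodels OLS after an explicit rank check
(rank-deficient designs raise an error naming the collinear columns, found
by leave-one-column-out rank restoration). R² is computed on the fitting
scale (ln scale for FVC); residual SD = √(RSS/(n − p)) with p counting the
intercept. `refit_paper_models` fixes the published term sets — the original
covariate-selection path is unknown, so re-running selection would
manufacture false precision; an `exploratory` mode (backward/forward
partial-F at 0.05, age basis protected) is provided and clearly labelled
non-canonical. Because the measured ratio is definitionally
100·FEV1/FVC — a quotient of the two generated volumes — the ratio refits
describe that quotient; there are no generating "ratio coefficients" to
recover, and recovery claims apply to the four volume models.

Coefficient-recovery tolerance is stated per coefficient: within 3 standard
errors in ≥ 95% of seeded replicates. (A joint all-coefficients criterion at
3 SE would fail ~9% of replicates for a perfectly specified model with ~30
coefficients, so it is not a meaningful check.)

## Numerical conventions

- Heights in cm package-wide; ECSC converts to metres at the call site.
- BMI always derived from weight/height, never read from files.
- Percent-predicted values are never rounded before thresholding; reports
  round to 1 d.p.
- Cohort CSV round-trips are binary-exact (`%.17g` on write,
  `float_precision="round_trip"` on read).
- Best-maneuver selection takes max FEV1 and max FVC independently across
  maneuvers (the ratio is recomputed from the selected pair); >8 maneuvers
  warns, an empty set errors.
- All generators take integer seeds via `numpy.random.default_rng`; equal
  seeds give byte-identical cohorts and reports.
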