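"""Seeded synthetic cohorts with the statistical structure the analysis
assumes.

Healthy cohorts emulate the source study's demographics (sex-stratified
normal age/height/weight, truncated to plausible adult ranges) and generate
measured spirometry from the local prediction equations plus Gaussian
residual noise at the published residual SDs — FEV1 on the litre scale,
FVC on the natural-log scale.

COPD cohorts are built backwards from a target GOLD stage mix: a stage is
drawn per subject, percent-predicted FEV1 is drawn uniformly inside that
stage's band, and measured FVC is chosen so the measured ratio falls below
the 70% obstruction threshold.  Staging such a cohort with the local
equations recovers the drawn stages exactly, which makes every downstream
stage/agreement step testable without external data.

Demographics are drawn independently per subject (marginals only, no
age-height correlation) — a documented simplification that deflates refit R²
but leaves coefficient recovery unbiased.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortTable, Sex, Spirogram, Subject
from .errors import ConfigurationError
from .local import continuous_basis_coefficients

__all__ = [
    "SexDemographics",
    "CohortSpec",
    "CopdSpec",
    "generate_healthy",
    "generate_copd",
    "HEALTHY_DEFAULTS",
    "COPD_DEFAULTS",
]


@dataclass(frozen=True)
class SexDemographics:
    """Mean/SD of age, height and weight for one sex stratum."""

    age_mean: float
    age_sd: float
    height_mean: float
    height_sd: float
    weight_mean: float
    weight_sd: float


#: healthy-study demographics (sex-stratified means and SDs)
HEALTHY_DEFAULTS = {
    Sex.MALE: SexDemographics(46.92, 16.16, 175.80, 7.25, 84.90, 4.90),
    Sex.FEMALE: SexDemographics(48.20, 17.19, 162.69, 7.18, 69.70, 15.92),
}

#: COPD-cohort demographics
COPD_DEFAULTS = {
    Sex.MALE: SexDemographics(62.65, 12.82, 172.17, 6.54, 79.20, 15.73),
    Sex.FEMALE: SexDemographics(63.18, 14.00, 159.03, 6.56, 64.78, 12.00),
}

#: published residual SDs per (sex, outcome), on the fitting scale
NOISE_DEFAULTS = {
    (Sex.MALE, "fev1"): 0.38,
    (Sex.FEMALE, "fev1"): 0.28,
    (Sex.MALE, "ln_fvc"): 0.12,
    (Sex.FEMALE, "ln_fvc"): 0.13,
    (Sex.MALE, "ratio"): 6.82,
    (Sex.FEMALE, "ratio"): 8.45,
}


@dataclass
class CohortSpec:
    """Healthy-cohort generator settings; defaults emulate the source study
    (n=500, 239 men / 261 women)."""

    n: int = 500
    sex_fraction_male: float = 239 / 500
    demographics: dict = field(default_factory=lambda: dict(HEALTHY_DEFAULTS))
    noise: dict = field(default_factory=lambda: dict(NOISE_DEFAULTS))
    age_bounds: tuple[float, float] = (18.0, 89.0)
    height_bounds: tuple[float, float] = (140.0, 205.0)
    weight_bounds: tuple[float, float] = (40.0, 160.0)
    #: correlation between the FEV1 and ln(FVC) residuals of one subject.
    #: The marginal SDs are the published residual SDs either way; a positive
    #: correlation reflects that both indices come from the same maneuver and
    #: keeps FEV1 <= FVC violations to a negligible tail (which is resampled).
    noise_correlation: float = 0.8
    seed: int = 0
    variant: str = "corrected"

    def validate(self):
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if any(sd < 0 for sd in self.noise.values()):
            raise ConfigurationError("noise SDs must be nonnegative")
        for lo, hi in (self.age_bounds, self.height_bounds, self.weight_bounds):
            if lo >= hi:
                raise ConfigurationError(f"infeasible truncation bounds ({lo}, {hi})")


@dataclass
class CopdSpec:
    """COPD-cohort generator settings; default stage mix follows the source
    study's 124-patient local-equation staging margins 17:44:42:21."""

    n: int = 124
    sex_fraction_male: float = 84 / 124
    demographics: dict = field(default_factory=lambda: dict(COPD_DEFAULTS))
    stage_mix: tuple[float, ...] = (17 / 124, 44 / 124, 42 / 124, 21 / 124)
    age_bounds: tuple[float, float] = (24.0, 91.0)
    height_bounds: tuple[float, float] = (140.0, 205.0)
    weight_bounds: tuple[float, float] = (40.0, 160.0)
    #: measured-ratio band, percent; upper end below the 70% obstruction gate
    ratio_band: tuple[float, float] = (40.0, 69.0)
    #: stage-1 percent-predicted draws are capped here rather than unbounded
    stage1_cap: float = 95.0
    seed: int = 0
    variant: str = "corrected"

    def validate(self):
        if self.n < 4:
            raise ConfigurationError("n must be >= 4")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9 or len(self.stage_mix) != 4:
            raise ConfigurationError("stage_mix must be 4 proportions summing to 1")
        if not 0 < self.ratio_band[0] < self.ratio_band[1] < 70:
            raise ConfigurationError("ratio_band must lie inside (0, 70)")


def _draw_truncnorm(rng, mean, sd, bounds, size):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    if a >= b:
        raise ConfigurationError(f"infeasible truncation bounds {bounds}")
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_demographics(rng, spec, sexes):
    ages = np.empty(len(sexes))
    heights = np.empty(len(sexes))
    weights = np.empty(len(sexes))
    for sex in (Sex.MALE, Sex.FEMALE):
        mask = sexes == (sex is Sex.MALE)
        k = int(mask.sum())
        if k == 0:
            continue
        d = spec.demographics[sex]
        ages[mask] = _draw_truncnorm(rng, d.age_mean, d.age_sd, spec.age_bounds, k)
        heights[mask] = _draw_truncnorm(
            rng, d.height_mean, d.height_sd, spec.height_bounds, k
        )
        weights[mask] = _draw_truncnorm(
            rng, d.weight_mean, d.weight_sd, spec.weight_bounds, k
        )
    return ages, heights, weights


def _basis_eval(coef: dict, age, height, weight):
    """Evaluate the continuous piecewise-basis form of a local equation."""
    return (
        coef["intercept"]
        + coef["age_young"] * np.minimum(age, 25.0)
        + coef["age_old"] * np.maximum(age - 25.0, 0.0)
        + coef["H"] * height
        + coef["H2"] * height**2
        + coef["W"] * weight
    )


def generate_healthy(spec: CohortSpec | None = None) -> CohortTable:
    """Generate a healthy cohort; fully reproducible given ``spec.seed``."""
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sexes = rng.random(spec.n) < spec.sex_fraction_male  # True = male
    ages, heights, weights = _draw_demographics(rng, spec, sexes)

    rho = spec.noise_correlation
    if not -1.0 < rho < 1.0:
        raise ConfigurationError("noise_correlation must lie in (-1, 1)")

    rows = []
    for i in range(spec.n):
        sex = Sex.MALE if sexes[i] else Sex.FEMALE
        cf = continuous_basis_coefficients(sex, "fev1", spec.variant)
        cv = continuous_basis_coefficients(sex, "ln_fvc", spec.variant)
        age, height, weight = ages[i], heights[i], weights[i]
        mu_fev1 = _basis_eval(cf, age, height, weight)
        mu_ln_fvc = _basis_eval(cv, age, height, weight)
        sd1 = spec.noise[(sex, "fev1")]
        sd2 = spec.noise[(sex, "ln_fvc")]
        # correlated residual pair with the published marginal SDs; the noise
        # is deliberately NOT truncated at FEV1 = FVC, so refits see exactly
        # Gaussian residuals (a small tail of spirograms is incoherent)
        z1 = rng.standard_normal()
        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal()
        fvc = math.exp(mu_ln_fvc + sd2 * z2)
        fev1 = max(mu_fev1 + sd1 * z1, 0.05)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spiro = Spirogram(fev1_l=float(fev1), fvc_l=float(fvc))
        rows.append(
            (
                Subject(
                    id=f"H{i:05d}",
                    sex=sex,
                    age_years=float(age),
                    height_cm=float(height),
                    weight_kg=float(weight),
                ),
                spiro,
            )
        )
    return CohortTable(rows=rows, provenance=f"synthetic-healthy(seed={spec.seed})")


def generate_copd(spec: CopdSpec | None = None) -> CohortTable:
    """Generate a COPD cohort whose local-equation staging equals the drawn
    target stages and whose measured ratios all sit below 70%."""
    from .local import predict_fev1_local

    spec = spec or CopdSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sexes = rng.random(spec.n) < spec.sex_fraction_male
    ages, heights, weights = _draw_demographics(rng, spec, sexes)
    stages = rng.choice(4, size=spec.n, p=list(spec.stage_mix)) + 1
    bands = {
        1: (80.0, spec.stage1_cap),
        2: (50.0, 80.0),
        3: (30.0, 50.0),
        4: (15.0, 30.0),
    }
    rows = []
    for i in range(spec.n):
        sex = Sex.MALE if sexes[i] else Sex.FEMALE
        # equations validated to age 95; the cohort can reach 91 by design
        age = float(np.clip(ages[i], 18.0, 95.0))
        pred = predict_fev1_local(sex, age, float(heights[i]), spec.variant)
        lo, hi = bands[int(stages[i])]
        pct = rng.uniform(lo, hi)
        fev1 = pct / 100.0 * pred
        ratio = rng.uniform(*spec.ratio_band)
        fvc = 100.0 * fev1 / ratio
        rows.append(
            (
                Subject(
                    id=f"C{i:05d}",
                    sex=sex,
                    age_years=age,
                    height_cm=float(heights[i]),
                    weight_kg=float(weights[i]),
                ),
                Spirogram(fev1_l=float(fev1), fvc_l=float(fvc)),
            )
        )
    return CohortTable(rows=rows, provenance=f"synthetic-copd(seed={spec.seed})")
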