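"""Sex-specific local (Greek-cohort) spirometric prediction equations.

Three outcomes are modelled per sex on a healthy adult cohort:

* FEV1 (litres): piecewise-linear in age with a knot at 25 years, linear
  (women) or linear+quadratic (men) in height.
* FVC: modelled on the natural-log scale, piecewise-linear in age, quadratic
  in height, with a negative weight term; predictions are exponentiated back
  to litres.
* FEV1/FVC (percent): a function of age only — linear for men, quadratic for
  women.

Each equation is published as two display branches (age < 25 and age ≥ 25).
The coefficient table ships in two variants: ``"corrected"`` (default), which
fixes a sign typo in the young-branch height-quadratic term of the male
ln(FVC) model (the printed ``+0.00041·H²`` makes predicted FVC astronomically
large; the negative sign matches the older branch and the female model), and
``"as_printed"``, which preserves the source text verbatim.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .cohort import Sex, Subject, PredictionSet
from .errors import ConfigurationError, RangeError

__all__ = [
    "load_local_coefficients",
    "predict_fev1_local",
    "predict_ln_fvc_local",
    "predict_fvc_local",
    "predict_ratio_local",
    "local_predict",
    "continuous_basis_coefficients",
    "predicted_ratio_moments",
    "residual_sd",
    "KNOT_AGE",
]

KNOT_AGE = 25.0

_AGE_RANGE = (18.0, 95.0)
_HEIGHT_RANGE = (120.0, 220.0)


@lru_cache(maxsize=4)
def load_local_coefficients(variant: str = "corrected") -> dict:
    """Load the packaged coefficient table as ``{(sex, outcome): {term: value}}``.

    ``variant`` selects ``"corrected"`` or ``"as_printed"`` rows; terms marked
    ``both`` apply to either variant.
    """
    if variant not in ("corrected", "as_printed"):
        raise ConfigurationError(f"unknown coefficient variant {variant!r}")
    with resources.files("spiroref.data").joinpath("local_equations.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df = df[df["variant"].isin(["both", variant])]
    table: dict = {}
    for (sex, outcome), grp in df.groupby(["sex", "outcome"]):
        table[(Sex(sex), outcome)] = dict(zip(grp["term"], grp["coefficient"]))
    return table


def _check_range(age: float, height: float | None = None) -> None:
    if not _AGE_RANGE[0] <= age <= _AGE_RANGE[1]:
        raise RangeError(f"age {age} outside validated range {_AGE_RANGE}")
    if height is not None and not _HEIGHT_RANGE[0] <= height <= _HEIGHT_RANGE[1]:
        raise RangeError(f"height {height} outside validated range {_HEIGHT_RANGE}")


def _piecewise_value(
    c: dict, age: float, height: float, weight: float | None
) -> float:
    """Evaluate one published two-branch model at (age, height[, weight]).

    Ages below the knot use the young branch; the knot itself belongs to the
    old branch.
    """
    young = age < KNOT_AGE
    b = "young" if young else "old"
    value = c[f"intercept_{b}"]
    value += c[f"age_slope_{b}"] * (age if young else age - KNOT_AGE)
    value += c.get("height_linear", 0.0) * height
    value += c.get(f"height_quadratic_{b}", 0.0) * height**2
    if "weight_linear" in c:
        if weight is None:
            raise TypeError("this equation requires weight")
        value += c["weight_linear"] * weight
    return value


def predict_fev1_local(
    sex: Sex, age: float, height: float, variant: str = "corrected"
) -> float:
    """Predicted FEV1 in litres from the local equations."""
    sex = Sex.parse(sex)
    _check_range(age, height)
    c = load_local_coefficients(variant)[(sex, "fev1")]
    return _piecewise_value(c, age, height, None)


def predict_ln_fvc_local(
    sex: Sex, age: float, height: float, weight: float, variant: str = "corrected"
) -> float:
    """Predicted natural log of FVC (the scale the model was fitted on)."""
    sex = Sex.parse(sex)
    _check_range(age, height)
    if weight is None:
        raise TypeError("predict_fvc_local requires weight")
    c = load_local_coefficients(variant)[(sex, "ln_fvc")]
    return _piecewise_value(c, age, height, weight)


def predict_fvc_local(
    sex: Sex, age: float, height: float, weight: float, variant: str = "corrected"
) -> float:
    """Predicted FVC in litres (exponentiated from the ln-scale model)."""
    import math

    return math.exp(predict_ln_fvc_local(sex, age, height, weight, variant))


def predict_ratio_local(sex: Sex, age: float, variant: str = "corrected") -> float:
    """Predicted FEV1/FVC ratio in percent; a function of age only."""
    sex = Sex.parse(sex)
    _check_range(age)
    c = load_local_coefficients(variant)[(sex, "ratio")]
    value = c["intercept"] + c["age_linear"] * age
    value += c.get("age_quadratic", 0.0) * age**2
    return value


def local_predict(subject: Subject, variant: str = "corrected") -> PredictionSet:
    """All three local predictions for one subject as a :class:`PredictionSet`."""
    return PredictionSet(
        source="local",
        fev1_pred_l=predict_fev1_local(
            subject.sex, subject.age_years, subject.height_cm, variant
        ),
        fvc_pred_l=predict_fvc_local(
            subject.sex, subject.age_years, subject.height_cm, subject.weight_kg,
            variant,
        ),
        ratio_pred_pct=predict_ratio_local(subject.sex, subject.age_years, variant),
    )


def continuous_basis_coefficients(
    sex: Sex, outcome: str, variant: str = "corrected"
) -> dict:
    """Published two-branch coefficients re-expressed on the continuous
    piecewise basis ``{1, min(A,25), max(A−25,0), H, H², W}``.

    The conversion anchors the age ≥ 25 branch exactly (the bulk of an adult
    cohort) and keeps the printed young-age slope, so where the printed
    branches are continuous the young branch is also reproduced (to the 0.001
    rounding of the printed intercepts).  For the male ln(FVC) model the
    printed branches are discontinuous by ≈0.066 at the knot; the continuous
    representation deviates from the printed young branch by that amount.

    Returns ``{"intercept", "age_young", "age_old", "H", "H2", "W"}`` (volume
    outcomes; absent covariates map to 0) or ``{"intercept", "A", "A2"}``
    (ratio).
    """
    sex = Sex.parse(sex)
    c = load_local_coefficients(variant)[(sex, outcome)]
    if outcome == "ratio":
        return {
            "intercept": c["intercept"],
            "A": c["age_linear"],
            "A2": c.get("age_quadratic", 0.0),
        }
    return {
        "intercept": c["intercept_old"] - KNOT_AGE * c["age_slope_young"],
        "age_young": c["age_slope_young"],
        "age_old": c["age_slope_old"],
        "H": c.get("height_linear", 0.0),
        "H2": c.get("height_quadratic_old", 0.0),
        "W": c.get("weight_linear", 0.0),
    }


def predicted_ratio_moments(
    sex: Sex, mean_age: float, sd_age: float, variant: str = "corrected"
) -> tuple[float, float]:
    """Mean and SD of the predicted ratio over a population with normally
    distributed age.

    Because the ratio depends on age alone, the male (linear) model gives
    ``E = intercept + b·μ`` and ``SD = |b|·σ`` exactly; the female quadratic
    uses ``E[A²] = μ² + σ²`` and the normal-moment variance
    ``σ²(b + 2cμ)² + 2c²σ⁴``.
    """
    sex = Sex.parse(sex)
    c = load_local_coefficients(variant)[(sex, "ratio")]
    b = c["age_linear"]
    q = c.get("age_quadratic", 0.0)
    mean = c["intercept"] + b * mean_age + q * (mean_age**2 + sd_age**2)
    var = sd_age**2 * (b + 2 * q * mean_age) ** 2 + 2 * q**2 * sd_age**4
    return mean, var**0.5


def residual_sd(sex: Sex, outcome: str, variant: str = "corrected") -> float:
    """Published residual SD for one model, on its fitting scale."""
    sex = Sex.parse(sex)
    return load_local_coefficients(variant)[(sex, outcome)]["residual_sd"]
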