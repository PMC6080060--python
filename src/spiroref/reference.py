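"""External reference equations: ECSC-1993 linear models and a GLI-2012-style
LMS (lambda-mu-sigma) model driven by an age-indexed lookup table.

ECSC
----
The 1993 ECSC/ERS summary equations are linear in height (metres) and age
(years).  They apply to adults; for ages 18–25 the convention of the source
is followed and age is clamped to 25, so predictions are constant over that
span.

GLI / LMS
---------
The LMS framework models the reference distribution of a lung-function index
through three age- (and height-) dependent quantities: the median ``M``, the
coefficient of variation ``S`` and the Box-Cox skewness power ``L``::

    M = exp(a0 + a1·ln(height) + a2·ln(age) + Mspline(age))
    S = exp(p0 + p1·ln(age) + Sspline(age))
    z = ((y/M)**L − 1) / (L·S)
    LLN = M·(1 + L·S·z_0.05)**(1/L),   z_0.05 = −1.645

Spline values are tabulated on an age grid and linearly interpolated; no
extrapolation beyond the grid is performed.

The packaged lookup ``gli_lookup_synthetic.tsv`` is a synthetic stand-in for
the published GLI-2012 coefficient tables (which cannot be redistributed
here): it has the genuine functional form and realistic adult magnitudes, but
its numbers are not the official GLI coefficients.  Supply your own table via
the ``lookup`` argument to use real GLI coefficients.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import Sex, Subject, PredictionSet
from .errors import ConfigurationError, RangeError

__all__ = [
    "load_ecsc_coefficients",
    "ecsc_predict",
    "load_gli_lookup",
    "gli_lookup_version",
    "lms_parameters",
    "gli_predict",
    "gli_zscore",
    "ECSC_AGE_CLAMP",
    "Z_LLN",
]

ECSC_AGE_CLAMP = 25.0
Z_LLN = -1.645  # 5th centile of the standard normal


@lru_cache(maxsize=1)
def load_ecsc_coefficients() -> pd.DataFrame:
    with resources.files("spiroref.data").joinpath("ecsc_coefficients.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index(["sex", "outcome"])


def _ecsc_value(sex: Sex, outcome: str, age: float, height_cm: float) -> float:
    table = load_ecsc_coefficients()
    try:
        row = table.loc[(sex.value, outcome)]
    except KeyError:
        raise ConfigurationError(
            f"ECSC coefficients missing for ({sex.value}, {outcome})"
        ) from None
    age_eff = max(age, ECSC_AGE_CLAMP)
    return (
        row["height_slope_per_m"] * (height_cm / 100.0)
        + row["age_slope_per_yr"] * age_eff
        + row["intercept"]
    )


def ecsc_predict(sex: Sex, age: float, height_cm: float) -> PredictionSet:
    """ECSC-1993 predicted FEV1, FVC (litres) and ratio (percent).

    Heights are taken in centimetres for consistency with the rest of the
    package and converted to metres here, the scale the 1993 formulas use.
    """
    sex = Sex.parse(sex)
    if age < 18:
        raise RangeError(f"ECSC adult equations require age >= 18, got {age}")
    return PredictionSet(
        source="ecsc",
        fev1_pred_l=_ecsc_value(sex, "fev1", age, height_cm),
        fvc_pred_l=_ecsc_value(sex, "fvc", age, height_cm),
        ratio_pred_pct=_ecsc_value(sex, "ratio", age, height_cm),
    )


@lru_cache(maxsize=1)
def load_gli_lookup() -> pd.DataFrame:
    """Load the packaged (synthetic stand-in) LMS lookup table."""
    with resources.files("spiroref.data").joinpath(
        "gli_lookup_synthetic.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for (sex, outcome), grp in df.groupby(["sex", "outcome"]):
        ages = grp["age"].to_numpy()
        if not np.all(np.diff(ages) > 0):
            raise ConfigurationError(
                f"GLI lookup age grid not strictly increasing for "
                f"({sex}, {outcome})"
            )
    if not np.isfinite(df.select_dtypes("number").to_numpy()).all():
        raise ConfigurationError("GLI lookup contains non-finite values")
    return df


def gli_lookup_version(lookup: pd.DataFrame | None = None) -> str:
    df = load_gli_lookup() if lookup is None else lookup
    return str(df["version"].iloc[0])


def lms_parameters(
    sex: Sex,
    outcome: str,
    age: float,
    height_cm: float,
    lookup: pd.DataFrame | None = None,
) -> tuple[float, float, float]:
    """Interpolated (M, S, L) for one sex/outcome at (age, height).

    Spline values (and L) are linearly interpolated in age between grid rows;
    ages outside the grid raise a range error.
    """
    sex = Sex.parse(sex)
    df = load_gli_lookup() if lookup is None else lookup
    grp = df[(df["sex"] == sex.value) & (df["outcome"] == outcome)]
    if grp.empty:
        raise ConfigurationError(f"no GLI rows for ({sex.value}, {outcome})")
    ages = grp["age"].to_numpy()
    if not ages[0] <= age <= ages[-1]:
        raise RangeError(
            f"age {age} outside GLI lookup grid [{ages[0]}, {ages[-1]}]"
        )
    if height_cm <= 0:
        raise RangeError("height must be positive")
    mspline = float(np.interp(age, ages, grp["Mspline"].to_numpy()))
    sspline = float(np.interp(age, ages, grp["Sspline"].to_numpy()))
    lvalue = float(np.interp(age, ages, grp["L"].to_numpy()))
    row = grp.iloc[0]  # a0..a2, p0, p1 are constant per (sex, outcome)
    m = math.exp(
        row["a0"] + row["a1"] * math.log(height_cm) + row["a2"] * math.log(age) + mspline
    )
    s = math.exp(row["p0"] + row["p1"] * math.log(age) + sspline)
    return m, s, lvalue


def _lln(m: float, s: float, lvalue: float) -> float:
    return m * (1 + lvalue * s * Z_LLN) ** (1 / lvalue)


def gli_predict(
    sex: Sex,
    age: float,
    height_cm: float,
    lookup: pd.DataFrame | None = None,
) -> PredictionSet:
    """LMS-predicted FEV1, FVC, ratio plus the FEV1 lower limit of normal.

    The ratio is predicted from its own LMS lookup, not as the quotient of
    the predicted volumes, matching GLI practice.
    """
    sex = Sex.parse(sex)
    m_fev1, s_fev1, l_fev1 = lms_parameters(sex, "fev1", age, height_cm, lookup)
    m_fvc, _, _ = lms_parameters(sex, "fvc", age, height_cm, lookup)
    m_ratio, _, _ = lms_parameters(sex, "ratio", age, height_cm, lookup)
    return PredictionSet(
        source="gli",
        fev1_pred_l=m_fev1,
        fvc_pred_l=m_fvc,
        ratio_pred_pct=m_ratio,
        lln_fev1_l=_lln(m_fev1, s_fev1, l_fev1),
    )


def gli_zscore(
    sex: Sex,
    outcome: str,
    measured: float,
    age: float,
    height_cm: float,
    lookup: pd.DataFrame | None = None,
) -> float:
    """LMS z-score of a measured value against the reference distribution."""
    m, s, lvalue = lms_parameters(sex, outcome, age, height_cm, lookup)
    return ((measured / m) ** lvalue - 1) / (lvalue * s)


def predict(subject: Subject, source: str, variant: str = "corrected") -> PredictionSet:
    """Dispatch a prediction for one subject by source name."""
    from .local import local_predict

    if source == "local":
        return local_predict(subject, variant=variant)
    if source == "ecsc":
        return ecsc_predict(subject.sex, subject.age_years, subject.height_cm)
    if source == "gli":
        ps = gli_predict(subject.sex, subject.age_years, subject.height_cm)
        return PredictionSet(
            source="gli",
            fev1_pred_l=ps.fev1_pred_l,
            fvc_pred_l=ps.fvc_pred_l,
            ratio_pred_pct=ps.ratio_pred_pct,
            lln_fev1_l=ps.lln_fev1_l,
            zscore_fev1=None,
        )
    raise ConfigurationError(f"unknown prediction source {source!r}")
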