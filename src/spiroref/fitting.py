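"""Re-derivation of the local prediction equations from cohort data.

The age effect enters as a continuous piecewise-linear term with a fixed knot
at 25 years: basis columns ``age_young = min(A, 25)`` and
``age_old = max(A − 25, 0)``.  FVC is fitted on the natural-log scale.  Fits
are ordinary least squares (delegated to statsmodels); fit statistics are
R² on the fitting scale and the residual SD ``sqrt(RSS / (n − p))`` with p
counting the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable, Sex
from .errors import SingularDesignError
from .local import KNOT_AGE

__all__ = [
    "ModelSpec",
    "FittedModel",
    "build_design",
    "fit_ols",
    "refit_paper_models",
    "two_branch_form",
    "CANONICAL_TERMS",
]

#: basis term label -> column builder on a cohort frame
_TERM_BUILDERS = {
    "age_young": lambda d: np.minimum(d["age_years"], KNOT_AGE),
    "age_old": lambda d: np.maximum(d["age_years"] - KNOT_AGE, 0.0),
    "H": lambda d: d["height_cm"],
    "H2": lambda d: d["height_cm"] ** 2,
    "W": lambda d: d["weight_kg"],
    "A": lambda d: d["age_years"],
    "A2": lambda d: d["age_years"] ** 2,
}

#: published final term sets per (sex, outcome)
CANONICAL_TERMS = {
    (Sex.MALE, "fev1"): ["age_young", "age_old", "H", "H2"],
    (Sex.FEMALE, "fev1"): ["age_young", "age_old", "H"],
    (Sex.MALE, "ln_fvc"): ["age_young", "age_old", "H", "H2", "W"],
    (Sex.FEMALE, "ln_fvc"): ["age_young", "age_old", "H", "H2", "W"],
    (Sex.MALE, "ratio"): ["A"],
    (Sex.FEMALE, "ratio"): ["A", "A2"],
}


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, basis terms and stratum of one regression model."""

    outcome: str  # "fev1" | "ln_fvc" | "ratio"
    terms: tuple[str, ...]
    sex: Sex

    def __post_init__(self):
        if self.outcome not in ("fev1", "ln_fvc", "ratio"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        unknown = [t for t in self.terms if t not in _TERM_BUILDERS]
        if unknown:
            raise ValueError(f"unknown basis term(s): {unknown}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate basis terms")
        object.__setattr__(self, "terms", tuple(self.terms))


@dataclass
class FittedModel:
    spec: ModelSpec
    coefficients: dict[str, float]  # includes "intercept"
    r_squared: float
    residual_sd: float
    n: int
    standard_errors: dict[str, float] = field(default_factory=dict)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Evaluate the fitted model on a cohort frame (fitting scale)."""
        x = self.coefficients["intercept"] * np.ones(len(frame))
        for t in self.spec.terms:
            x = x + self.coefficients[t] * np.asarray(_TERM_BUILDERS[t](frame), float)
        return x

    def to_dict(self) -> dict:
        return {
            "sex": self.spec.sex.value,
            "outcome": self.spec.outcome,
            "terms": list(self.spec.terms),
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "n": self.n,
        }


def build_design(cohort: CohortTable | pd.DataFrame, spec: ModelSpec):
    """Design matrix (leading intercept column, then terms in spec order) and
    response vector for one model.

    For ``ln_fvc`` the response is the natural log of measured FVC; for a
    bare frame the measured columns ``fev1_l``/``fvc_l`` must be present.
    """
    frame = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort
    if isinstance(cohort, CohortTable):
        frame = frame[frame["sex"] == ("M" if spec.sex is Sex.MALE else "F")]
    needed = {"age_young": "age_years", "age_old": "age_years", "A": "age_years",
              "A2": "age_years", "H": "height_cm", "H2": "height_cm",
              "W": "weight_kg"}
    for t in spec.terms:
        col = needed[t]
        if col not in frame.columns or frame[col].isna().any():
            raise ValueError(f"covariate {col!r} required by term {t!r} is missing")
    cols = [np.ones(len(frame))]
    for t in spec.terms:
        cols.append(np.asarray(_TERM_BUILDERS[t](frame), dtype=float))
    design = np.column_stack(cols)
    if spec.outcome == "fev1":
        response = frame["fev1_l"].to_numpy(float)
    elif spec.outcome == "ln_fvc":
        response = np.log(frame["fvc_l"].to_numpy(float))
    else:
        response = 100.0 * frame["fev1_l"].to_numpy(float) / frame["fvc_l"].to_numpy(float)
    return design, response


def fit_ols(design: np.ndarray, response: np.ndarray, spec: ModelSpec) -> FittedModel:
    """Ordinary least squares with rank-deficiency detection.

    A rank-deficient design raises :class:`SingularDesignError` naming the
    collinear columns (those whose removal restores full rank).
    """
    design = np.asarray(design, float)
    response = np.asarray(response, float)
    n, p = design.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        names = ["intercept"] + list(spec.terms)
        collinear = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise SingularDesignError(collinear or names)
    res = sm.OLS(response, design).fit()
    names = ["intercept"] + list(spec.terms)
    rss = float(res.ssr)
    tss = float(((response - response.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    return FittedModel(
        spec=spec,
        coefficients=dict(zip(names, map(float, res.params))),
        r_squared=r2,
        residual_sd=float(np.sqrt(rss / (n - p))),
        n=n,
        standard_errors=dict(zip(names, map(float, res.bse))),
    )


def fit_model(cohort, spec: ModelSpec) -> FittedModel:
    design, response = build_design(cohort, spec)
    return fit_ols(design, response, spec)


def refit_paper_models(
    cohort: CohortTable, exploratory: bool = False, min_per_sex: int = 50
) -> dict[tuple[Sex, str], FittedModel]:
    """Fit the six published sex × outcome models on a cohort.

    The canonical mode fixes the published final term sets (no covariate
    selection), which is the reproducible choice since the original selection
    path is unknown.  ``exploratory=True`` instead prunes/extends each term
    set by partial-F tests at the 0.05 level — explicitly non-canonical, for
    sensitivity analysis only.
    """
    for sex in (Sex.MALE, Sex.FEMALE):
        n_sex = len(cohort.subset(sex))
        if n_sex < min_per_sex:
            raise ValueError(
                f"stratum '{sex.value}' has {n_sex} subjects; need >= {min_per_sex}"
            )
    results: dict[tuple[Sex, str], FittedModel] = {}
    for (sex, outcome), terms in CANONICAL_TERMS.items():
        spec = ModelSpec(outcome=outcome, terms=tuple(terms), sex=sex)
        if exploratory:
            spec = _explore_terms(cohort, spec)
        results[(sex, outcome)] = fit_model(cohort, spec)
    return results


def _explore_terms(cohort, spec: ModelSpec, alpha: float = 0.05) -> ModelSpec:
    """Backward-then-forward term selection by partial-F (equivalently the
    coefficient t-test for one term).  Non-canonical; age terms are protected
    so the piecewise structure survives."""
    protected = {"age_young", "age_old", "A"}
    pool = {"H", "H2", "W"} if spec.outcome != "ratio" else {"A2"}
    terms = list(spec.terms)
    changed = True
    while changed:
        changed = False
        # backward pass
        for t in [t for t in terms if t not in protected]:
            fm = fit_model(cohort, ModelSpec(spec.outcome, tuple(terms), spec.sex))
            design, response = build_design(
                cohort, ModelSpec(spec.outcome, tuple(terms), spec.sex)
            )
            res = sm.OLS(response, design).fit()
            idx = 1 + terms.index(t)
            if res.pvalues[idx] > alpha:
                terms.remove(t)
                changed = True
                break
        if changed:
            continue
        # forward pass
        for t in sorted(pool - set(terms)):
            cand = terms + [t]
            design, response = build_design(
                cohort, ModelSpec(spec.outcome, tuple(cand), spec.sex)
            )
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue
            res = sm.OLS(response, design).fit()
            if res.pvalues[-1] <= alpha:
                terms = cand
                changed = True
                break
    return ModelSpec(spec.outcome, tuple(terms), spec.sex)


def two_branch_form(model: FittedModel) -> dict:
    """Re-express a piecewise-basis fit in the published two-branch display
    form: ``intercept_young + age_slope_young·A`` below the knot and
    ``intercept_old + age_slope_old·(A−25)`` at or above it, plus the shared
    covariate slopes."""
    c = model.coefficients
    if "age_young" not in c or "age_old" not in c:
        raise ValueError("model has no piecewise age basis")
    shared = {
        k: v for k, v in c.items() if k not in ("intercept", "age_young", "age_old")
    }
    return {
        "intercept_young": c["intercept"],
        "age_slope_young": c["age_young"],
        "intercept_old": c["intercept"] + KNOT_AGE * c["age_young"],
        "age_slope_old": c["age_old"],
        **shared,
    }
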