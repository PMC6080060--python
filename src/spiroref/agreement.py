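"""GOLD spirometric staging and the between-source agreement battery.

Staging follows the GOLD percent-predicted conventions with half-open bands:
stage 1 (mild) at ≥80% predicted FEV1, stage 2 (moderate) in [50, 80),
stage 3 (severe) in [30, 50), stage 4 (very severe) below 30%.  Percent
predicted is never rounded before thresholding.  An optional obstruction gate
applies the fixed-ratio definition (measured FEV1/FVC < 70%) before staging.

Agreement between two stagings is summarised by percent agreement, Cohen's
kappa (unweighted, linear- or quadratic-weighted) on the 4×4 cross-tabulation,
and — for continuous indices — Lin's concordance correlation coefficient.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable
from .errors import UndefinedStatisticWarning

__all__ = [
    "GoldStage",
    "NO_LIMITATION",
    "StageCrossTab",
    "AgreementReport",
    "ConcordanceReport",
    "gold_stage",
    "stage_cohort",
    "cross_tabulate",
    "percent_agreement",
    "cohen_kappa",
    "agreement_report",
    "lins_ccc",
    "STAGE_BANDS",
]

#: stage → [lower, upper) percent-predicted band; stage 1's upper bound is open
STAGE_BANDS = {1: (80.0, np.inf), 2: (50.0, 80.0), 3: (30.0, 50.0), 4: (0.0, 30.0)}

#: fixed-ratio obstruction threshold, percent
OBSTRUCTION_RATIO_PCT = 70.0


class GoldStage(enum.IntEnum):
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    VERY_SEVERE = 4


#: sentinel outcome when the obstruction gate is not met
NO_LIMITATION = None


def gold_stage(
    measured_fev1: float,
    predicted_fev1: float,
    measured_ratio: float | None = None,
    require_obstruction: bool = False,
) -> GoldStage | None:
    """Stage airflow-limitation severity from percent-predicted FEV1.

    Returns ``None`` ("no airflow limitation") when ``require_obstruction``
    is set and the measured ratio is at or above 70%.  When staging a cohort
    already diagnosed as COPD the gate is normally left off.
    """
    if predicted_fev1 <= 0:
        raise ValueError(f"predicted FEV1 must be positive, got {predicted_fev1}")
    if require_obstruction:
        if measured_ratio is None:
            raise ValueError("require_obstruction needs the measured ratio")
        if measured_ratio >= OBSTRUCTION_RATIO_PCT:
            return NO_LIMITATION
    pct = 100.0 * measured_fev1 / predicted_fev1
    if pct >= 80.0:
        return GoldStage.MILD
    if pct >= 50.0:
        return GoldStage.MODERATE
    if pct >= 30.0:
        return GoldStage.SEVERE
    return GoldStage.VERY_SEVERE


def stage_cohort(
    cohort: CohortTable,
    source: str,
    require_obstruction: bool = False,
    variant: str = "corrected",
) -> list[GoldStage | None]:
    """Stage every subject of a cohort under one prediction source."""
    from .reference import predict

    stages = []
    for subject, spiro in cohort:
        ps = predict(subject, source, variant=variant)
        stages.append(
            gold_stage(
                spiro.fev1_l,
                ps.fev1_pred_l,
                measured_ratio=spiro.ratio_pct,
                require_obstruction=require_obstruction,
            )
        )
    return stages


@dataclass
class StageCrossTab:
    """Labelled 4×4 contingency table of stages under two sources."""

    counts: np.ndarray
    row_source: str = "a"
    col_source: str = "b"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4):
            raise ValueError(f"expected a 4x4 table, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("table must contain at least one subject")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def diagonal(self) -> int:
        return int(np.trace(self.counts))

    def transpose(self) -> "StageCrossTab":
        return StageCrossTab(
            self.counts.T, row_source=self.col_source, col_source=self.row_source
        )


def cross_tabulate(
    stages_a, stages_b, row_source: str = "a", col_source: str = "b"
) -> StageCrossTab:
    """Cross-tabulate two aligned stage vectors into a 4×4 count table."""
    stages_a = list(stages_a)
    stages_b = list(stages_b)
    if len(stages_a) != len(stages_b):
        raise ValueError(
            f"stage vectors differ in length: {len(stages_a)} vs {len(stages_b)}"
        )
    counts = np.zeros((4, 4), dtype=int)
    for a, b in zip(stages_a, stages_b):
        if a is NO_LIMITATION or b is NO_LIMITATION:
            raise ValueError(
                "cross_tabulate expects staged subjects only; filter "
                "no-limitation outcomes first"
            )
        counts[int(a) - 1, int(b) - 1] += 1
    return StageCrossTab(counts, row_source=row_source, col_source=col_source)


def percent_agreement(tab: StageCrossTab) -> tuple[float, int]:
    """Diagonal (exact-agreement) percentage and count."""
    return 100.0 * tab.diagonal / tab.n, tab.diagonal


def _weight_matrix(k: int, weighting: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if weighting == "none":
        return (i == j).astype(float)
    if weighting == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if weighting == "quadratic":
        return 1.0 - (i - j) ** 2 / (k - 1) ** 2
    raise ValueError(f"unknown weighting {weighting!r}")


def cohen_kappa(tab: StageCrossTab, weighting: str = "linear") -> float:
    """Cohen's kappa on a stage cross-tabulation.

    With agreement weights ``w_ij`` (identity, ``1−|i−j|/(k−1)`` or
    ``1−(i−j)²/(k−1)²``)::

        κ = (Σ w·p_obs − Σ w·p_exp) / (1 − Σ w·p_exp)

    where expected proportions come from the marginal products.  Linear
    weights are the package default: they reproduce the published agreement
    coefficients from the published cross-tabulations, which unweighted kappa
    does not.  Degenerate marginals (all mass in one category on both axes)
    make kappa undefined; NaN is returned with a warning.
    """
    counts = tab.counts.astype(float)
    n = counts.sum()
    k = counts.shape[0]
    w = _weight_matrix(k, weighting)
    p_obs = (w * counts).sum() / n
    p_exp = (w * np.outer(counts.sum(axis=1), counts.sum(axis=0))).sum() / n**2
    denom = 1.0 - p_exp
    if abs(denom) < 1e-12:
        warnings.warn(
            "kappa undefined: expected agreement is 1 (degenerate marginals)",
            UndefinedStatisticWarning,
            stacklevel=2,
        )
        return float("nan")
    return (p_obs - p_exp) / denom


@dataclass
class AgreementReport:
    """Percent agreement and the kappa family for one cross-tabulation."""

    percent_agreement: float
    diagonal: int
    n: int
    kappa_unweighted: float
    kappa_linear: float
    kappa_quadratic: float
    row_source: str = "a"
    col_source: str = "b"

    def to_dict(self) -> dict:
        return {
            "row_source": self.row_source,
            "col_source": self.col_source,
            "n": self.n,
            "diagonal": self.diagonal,
            "percent_agreement": self.percent_agreement,
            "kappa_unweighted": self.kappa_unweighted,
            "kappa_linear": self.kappa_linear,
            "kappa_quadratic": self.kappa_quadratic,
        }


def agreement_report(tab: StageCrossTab) -> AgreementReport:
    pct, diag = percent_agreement(tab)
    return AgreementReport(
        percent_agreement=pct,
        diagonal=diag,
        n=tab.n,
        kappa_unweighted=cohen_kappa(tab, "none"),
        kappa_linear=cohen_kappa(tab, "linear"),
        kappa_quadratic=cohen_kappa(tab, "quadratic"),
        row_source=tab.row_source,
        col_source=tab.col_source,
    )


@dataclass
class ConcordanceReport:
    """Lin's concordance plus companion statistics for two paired vectors."""

    lins_ccc: float
    pearson_r: float
    r_squared: float
    average_difference: float
    n: int = 0


def lins_ccc(x, y, estimator: str = "population") -> ConcordanceReport:
    """Lin's concordance correlation coefficient between paired vectors.

    ::

        ρc = 2·cov(x, y) / (var(x) + var(y) + (mean x − mean y)²)

    Moments use 1/n (population) estimators per the original definition;
    ``estimator="sample"`` selects 1/(n−1).  The report also carries Pearson
    r, r² and the mean difference x − y (callers adopt the
    predicted-minus-measured convention by passing predictions as ``x``).
    Zero variance in either vector makes the statistic undefined → NaN with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    ddof = 0 if estimator == "population" else 1
    if estimator not in ("population", "sample"):
        raise ValueError(f"unknown estimator {estimator!r}")
    var_x = x.var(ddof=ddof)
    var_y = y.var(ddof=ddof)
    mean_diff = float(x.mean() - y.mean())
    if var_x == 0 or var_y == 0:
        warnings.warn(
            "concordance undefined: zero variance in an input vector",
            UndefinedStatisticWarning,
            stacklevel=2,
        )
        return ConcordanceReport(
            float("nan"), float("nan"), float("nan"), mean_diff, n
        )
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (n - ddof)
    ccc = 2 * cov / (var_x + var_y + mean_diff**2)
    r = cov / np.sqrt(var_x * var_y)
    return ConcordanceReport(
        lins_ccc=float(ccc),
        pearson_r=float(r),
        r_squared=float(r**2),
        average_difference=mean_diff,
        n=n,
    )
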