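"""Domain types and delimited-text I/O for spirometry cohorts.

A cohort is an ordered collection of ``(Subject, Spirogram)`` pairs.  Units
are fixed package-wide: age in years, height in centimetres, weight in
kilograms, volumes in litres, the FEV1/FVC ratio as a percentage.

The on-disk format is a UTF-8 comma-delimited file with header
``id,sex,age_years,height_cm,weight_kg,fev1_l,fvc_l``; sex is coded ``M``/``F``
(case-insensitive).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import CohortFormatError, CohortValidationError, RangeError

__all__ = [
    "Sex",
    "Subject",
    "Spirogram",
    "PredictionSet",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "select_best",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ["id", "sex", "age_years", "height_cm", "weight_kg", "fev1_l", "fvc_l"]

#: validated input box for the prediction equations
AGE_RANGE = (18.0, 95.0)
HEIGHT_RANGE = (120.0, 220.0)
WEIGHT_RANGE = (30.0, 200.0)

#: measured FEV1 may exceed FVC by at most this fraction before a row is rejected
FEV1_OVER_FVC_TOLERANCE = 0.02


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value) -> "Sex":
        if isinstance(value, Sex):
            return value
        s = str(value).strip().lower()
        if s in ("m", "male"):
            return cls.MALE
        if s in ("f", "female"):
            return cls.FEMALE
        raise ValueError(f"unrecognised sex code {value!r} (expected M/F)")


@dataclass(frozen=True)
class Subject:
    """Demographics driving every prediction equation.

    ``weight_kg`` is optional because some equations (FEV1, the ratio) do not
    use it.  BMI is always derived, never stored.
    """

    id: str
    sex: Sex
    age_years: float
    height_cm: float
    weight_kg: float | None = None

    def __post_init__(self):
        if not AGE_RANGE[0] <= self.age_years <= AGE_RANGE[1]:
            raise RangeError(
                f"age {self.age_years} outside validated range {AGE_RANGE}"
            )
        if not HEIGHT_RANGE[0] <= self.height_cm <= HEIGHT_RANGE[1]:
            raise RangeError(
                f"height {self.height_cm} outside validated range {HEIGHT_RANGE}"
            )
        if self.weight_kg is not None and not (
            WEIGHT_RANGE[0] <= self.weight_kg <= WEIGHT_RANGE[1]
        ):
            raise RangeError(
                f"weight {self.weight_kg} outside validated range {WEIGHT_RANGE}"
            )

    @property
    def bmi(self) -> float | None:
        """Body-mass index in kg/m², derived from weight and height."""
        if self.weight_kg is None:
            return None
        return self.weight_kg / (self.height_cm / 100.0) ** 2


@dataclass(frozen=True)
class Spirogram:
    """Measured FEV1 and FVC (litres) for one test; ratio derived in percent."""

    fev1_l: float
    fvc_l: float

    def __post_init__(self):
        if not self.fev1_l > 0:
            raise ValueError(f"fev1 must be positive, got {self.fev1_l}")
        if not self.fvc_l > 0:
            raise ValueError(f"fvc must be positive, got {self.fvc_l}")
        if self.fev1_l > self.fvc_l:
            # tolerated at the type level (measurement/synthetic noise can
            # produce it); file readers reject rows beyond the 2% tolerance
            warnings.warn(
                f"fev1 ({self.fev1_l}) exceeds fvc ({self.fvc_l})",
                stacklevel=2,
            )

    @property
    def ratio_pct(self) -> float:
        return 100.0 * self.fev1_l / self.fvc_l


@dataclass(frozen=True)
class PredictionSet:
    """Predicted FEV1/FVC/ratio from one reference source.

    ``lln_fev1_l`` and ``zscore_fev1`` are populated only by sources that model
    the scatter of the reference population (GLI); they are ``None`` otherwise.
    """

    source: str  # "local" | "ecsc" | "gli"
    fev1_pred_l: float
    fvc_pred_l: float
    ratio_pred_pct: float
    lln_fev1_l: float | None = None
    zscore_fev1: float | None = None

    def __post_init__(self):
        if self.fev1_pred_l <= 0 or self.fvc_pred_l <= 0:
            raise ValueError("predicted volumes must be positive")
        if not 0 < self.ratio_pred_pct <= 120:
            raise ValueError(
                f"predicted ratio {self.ratio_pred_pct} outside (0, 120]"
            )


@dataclass
class CohortTable:
    """Ordered collection of (Subject, Spirogram) pairs with unique ids."""

    rows: list[tuple[Subject, Spirogram]] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [s.id for s, _ in self.rows]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def subset(self, sex: Sex) -> "CohortTable":
        return CohortTable(
            rows=[(s, sp) for s, sp in self.rows if s.sex is sex],
            provenance=f"{self.provenance}[{sex.value}]",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s, _ in self.rows],
                "sex": ["M" if s.sex is Sex.MALE else "F" for s, _ in self.rows],
                "age_years": [s.age_years for s, _ in self.rows],
                "height_cm": [s.height_cm for s, _ in self.rows],
                "weight_kg": [s.weight_kg for s, _ in self.rows],
                "fev1_l": [sp.fev1_l for _, sp in self.rows],
                "fvc_l": [sp.fvc_l for _, sp in self.rows],
            }
        )


def read_cohort(path, provenance: str | None = None) -> CohortTable:
    """Read a cohort file, validating every row.

    Rows failing type or range validation are rejected collectively: a
    :class:`CohortValidationError` carries ``(row_index, field, message)``
    diagnostics for each offending row.  A missing mandatory column raises
    :class:`CohortFormatError`.
    """
    try:
        df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortFormatError(f"cannot read cohort file {path}: {exc}") from exc

    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(
            f"cohort file {path} is missing mandatory column(s): {missing}"
        )

    rows: list[tuple[Subject, Spirogram]] = []
    row_errors: list[tuple[int, str, str]] = []
    for i, rec in enumerate(df.to_dict("records")):
        try:
            sex = Sex.parse(rec["sex"])
        except ValueError as exc:
            row_errors.append((i, "sex", str(exc)))
            continue
        numeric = {}
        bad = False
        for col in ("age_years", "height_cm", "weight_kg", "fev1_l", "fvc_l"):
            try:
                v = rec[col]
                numeric[col] = None if pd.isna(v) else float(v)
            except (TypeError, ValueError):
                row_errors.append((i, col, f"unparsable numeric value {rec[col]!r}"))
                bad = True
        if bad:
            continue
        if numeric["weight_kg"] is None:
            row_errors.append((i, "weight_kg", "missing value"))
            continue
        if (
            numeric["fev1_l"] is not None
            and numeric["fvc_l"] is not None
            and numeric["fvc_l"] > 0
            and numeric["fev1_l"] > numeric["fvc_l"] * (1 + FEV1_OVER_FVC_TOLERANCE)
        ):
            row_errors.append(
                (
                    i,
                    "fev1_l",
                    f"fev1 ({numeric['fev1_l']}) exceeds fvc ({numeric['fvc_l']}) "
                    f"by more than {FEV1_OVER_FVC_TOLERANCE:.0%}",
                )
            )
            continue
        try:
            subject = Subject(
                id=str(rec["id"]),
                sex=sex,
                age_years=numeric["age_years"],
                height_cm=numeric["height_cm"],
                weight_kg=numeric["weight_kg"],
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spiro = Spirogram(fev1_l=numeric["fev1_l"], fvc_l=numeric["fvc_l"])
        except (ValueError, TypeError) as exc:
            row_errors.append((i, "*", str(exc)))
            continue
        rows.append((subject, spiro))

    if row_errors:
        raise CohortValidationError(row_errors)
    return CohortTable(rows=rows, provenance=provenance or str(path))


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort back to the delimited format read by :func:`read_cohort`.

    Round-trips every field at full ``repr`` precision.
    """
    df = table.to_frame()
    # %.17g guarantees binary-exact float round-trips through the text format
    df.to_csv(path, index=False, float_format="%.17g")


def select_best(maneuvers) -> Spirogram:
    """Best-maneuver selection: the largest FEV1 and the largest FVC across
    all maneuvers, selected independently, with the ratio recomputed from the
    selected pair.

    Guidance-compliant sessions contain at most eight maneuvers; more than
    eight triggers a warning, an empty collection is an error.
    """
    maneuvers = list(maneuvers)
    if not maneuvers:
        raise ValueError("select_best requires at least one maneuver")
    if len(maneuvers) > 8:
        warnings.warn(
            f"{len(maneuvers)} maneuvers supplied; sessions normally contain "
            "at most eight",
            stacklevel=2,
        )
    best_fev1 = max(m.fev1_l for m in maneuvers)
    best_fvc = max(m.fvc_l for m in maneuvers)
    return Spirogram(fev1_l=best_fev1, fvc_l=best_fvc)
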