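"""End-to-end orchestration: predict under every source, stage, cross-tabulate,
and compute the agreement/concordance battery, with deterministic file output.

This module is the programmatic pipeline surface: build a :class:`RunConfig`,
call :func:`run_comparison`, and read the returned :class:`ReportBundle` (or
the CSV/JSON files it wrote).  Reports follow the predicted-minus-measured
sign convention for average differences.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .agreement import (
    AgreementReport,
    ConcordanceReport,
    StageCrossTab,
    agreement_report,
    cross_tabulate,
    lins_ccc,
    stage_cohort,
)
from .cohort import CohortTable, read_cohort
from .errors import ConfigurationError
from .reference import gli_lookup_version, predict

__all__ = ["RunConfig", "ReportBundle", "run_comparison"]

_VALID_SOURCES = ("local", "ecsc", "gli")


@dataclass
class RunConfig:
    """Configuration of one comparison run.

    Exactly one of ``cohort`` / ``cohort_path`` must be provided.  ``sources``
    is the ordered tuple of prediction sources to compare pairwise.
    """

    cohort: CohortTable | None = None
    cohort_path: str | Path | None = None
    sources: tuple[str, ...] = ("local", "ecsc", "gli")
    kappa_weighting: str = "linear"
    require_obstruction: bool = False
    coefficient_variant: str = "corrected"
    output_dir: str | Path | None = None
    seed: int = 0

    def validate(self):
        if (self.cohort is None) == (self.cohort_path is None):
            raise ConfigurationError(
                "provide exactly one of cohort / cohort_path"
            )
        if len(self.sources) < 2:
            raise ConfigurationError("need at least two sources to compare")
        if len(set(self.sources)) != len(self.sources):
            raise ConfigurationError(f"sources must be distinct: {self.sources}")
        unknown = [s for s in self.sources if s not in _VALID_SOURCES]
        if unknown:
            raise ConfigurationError(f"unknown source(s): {unknown}")
        if self.kappa_weighting not in ("none", "linear", "quadratic"):
            raise ConfigurationError(
                f"unknown kappa weighting {self.kappa_weighting!r}"
            )


@dataclass
class ReportBundle:
    """In-memory result of one run; mirrored to files when output_dir is set."""

    predictions: pd.DataFrame
    stages: pd.DataFrame
    crosstabs: dict[tuple[str, str], StageCrossTab]
    agreement: dict[tuple[str, str], AgreementReport]
    concordance: dict[tuple[str, str, str], ConcordanceReport]
    header: dict

    def summary_dict(self) -> dict:
        return {
            "header": self.header,
            "agreement": {
                f"{a}_vs_{b}": rep.to_dict() for (a, b), rep in self.agreement.items()
            },
            "concordance": {
                f"{key[0]}_vs_{key[1]}/{key[2]}": vars(rep)
                for key, rep in self.concordance.items()
            },
        }


def _prediction_frame(cohort: CohortTable, sources, variant) -> pd.DataFrame:
    records = []
    for subject, spiro in cohort:
        rec = {
            "id": subject.id,
            "sex": subject.sex.value,
            "age_years": subject.age_years,
            "height_cm": subject.height_cm,
            "weight_kg": subject.weight_kg,
            "fev1_measured_l": spiro.fev1_l,
            "fvc_measured_l": spiro.fvc_l,
            "ratio_measured_pct": spiro.ratio_pct,
        }
        for source in sources:
            ps = predict(subject, source, variant=variant)
            rec[f"fev1_{source}_l"] = ps.fev1_pred_l
            rec[f"fvc_{source}_l"] = ps.fvc_pred_l
            rec[f"ratio_{source}_pct"] = ps.ratio_pred_pct
            if ps.lln_fev1_l is not None:
                rec[f"lln_fev1_{source}_l"] = ps.lln_fev1_l
        records.append(rec)
    return pd.DataFrame(records)


def run_comparison(config: RunConfig) -> ReportBundle:
    """Run the full comparison pipeline.

    Per subject: predictions under every configured source and a GOLD stage
    under each; pairwise 4×4 cross-tabulations with the full agreement
    battery; Lin's concordance (predicted-minus-measured for predicted-vs-
    measured pairs, first-minus-second between sources) for FEV1, FVC and the
    ratio.  Deterministic given the same config; partial outputs are removed
    if any stage fails.
    """
    config.validate()
    cohort = (
        config.cohort
        if config.cohort is not None
        else read_cohort(config.cohort_path)
    )
    out = Path(config.output_dir) if config.output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        bundle = _run(config, cohort)
        if out is not None:
            _write_bundle(bundle, out)
        return bundle
    except Exception:
        if out is not None and out.exists():
            for p in out.glob("*"):
                if p.is_file():
                    p.unlink()
        raise


def _run(config: RunConfig, cohort: CohortTable) -> ReportBundle:
    variant = config.coefficient_variant
    header = {
        "n_subjects": len(cohort),
        "provenance": cohort.provenance,
        "sources": list(config.sources),
        "kappa_weighting": config.kappa_weighting,
        "coefficient_variant": variant,
        "gli_lookup_version": (
            gli_lookup_version() if "gli" in config.sources else None
        ),
        "require_obstruction": config.require_obstruction,
        "seed": config.seed,
    }
    predictions = _prediction_frame(cohort, config.sources, variant)

    stage_vectors = {
        source: stage_cohort(
            cohort,
            source,
            require_obstruction=config.require_obstruction,
            variant=variant,
        )
        for source in config.sources
    }
    stages = pd.DataFrame(
        {
            "id": predictions["id"],
            **{
                f"stage_{s}": [None if st is None else int(st) for st in v]
                for s, v in stage_vectors.items()
            },
        }
    )

    crosstabs = {}
    agreement = {}
    for a, b in itertools.combinations(config.sources, 2):
        keep = [
            (sa, sb)
            for sa, sb in zip(stage_vectors[a], stage_vectors[b])
            if sa is not None and sb is not None
        ]
        tab = cross_tabulate(
            [sa for sa, _ in keep], [sb for _, sb in keep], row_source=a, col_source=b
        )
        crosstabs[(a, b)] = tab
        agreement[(a, b)] = agreement_report(tab)

    concordance = {}
    for outcome, meas_col in (
        ("fev1", "fev1_measured_l"),
        ("fvc", "fvc_measured_l"),
        ("ratio", "ratio_measured_pct"),
    ):
        unit = "l" if outcome != "ratio" else "pct"
        for source in config.sources:
            concordance[(source, "measured", outcome)] = lins_ccc(
                predictions[f"{outcome}_{source}_{unit}"], predictions[meas_col]
            )
        for a, b in itertools.combinations(config.sources, 2):
            concordance[(a, b, outcome)] = lins_ccc(
                predictions[f"{outcome}_{a}_{unit}"],
                predictions[f"{outcome}_{b}_{unit}"],
            )

    return ReportBundle(
        predictions=predictions,
        stages=stages,
        crosstabs=crosstabs,
        agreement=agreement,
        concordance=concordance,
        header=header,
    )


def _write_bundle(bundle: ReportBundle, out: Path) -> None:
    bundle.predictions.to_csv(out / "predictions.csv", index=False)
    bundle.stages.to_csv(out / "stages.csv", index=False)
    labels = ["mild", "moderate", "severe", "very_severe"]
    for (a, b), tab in bundle.crosstabs.items():
        df = pd.DataFrame(tab.counts, index=labels, columns=labels)
        df.index.name = "stage"
        df.to_csv(out / f"crosstab_{a}_vs_{b}.tsv", sep="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle.summary_dict(), fh, indent=2, sort_keys=True)
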