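"""Loaders for the packaged data tables.

Three published GOLD-staging cross-tabulations of the 124-patient COPD
cohort ship as tab-delimited fixtures, keyed by the pair of prediction
sources being compared:

* ``"local_vs_ecsc"`` — local-equation staging (rows) vs ECSC (columns)
* ``"local_vs_gli"``  — local (rows) vs GLI (columns)
* ``"ecsc_vs_gli"``   — ECSC (rows) vs GLI (columns)
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .agreement import StageCrossTab

__all__ = ["STAGE_CROSSTAB_NAMES", "load_stage_crosstab", "read_crosstab_file"]

STAGE_CROSSTAB_NAMES = ("local_vs_ecsc", "local_vs_gli", "ecsc_vs_gli")

_STAGE_LABELS = ["mild", "moderate", "severe", "very_severe"]


def _parse_crosstab(df: pd.DataFrame, row_source: str, col_source: str) -> StageCrossTab:
    df = df.set_index("stage")
    missing = [s for s in _STAGE_LABELS if s not in df.index or s not in df.columns]
    if missing:
        raise ValueError(f"crosstab is missing stage label(s): {missing}")
    counts = df.loc[_STAGE_LABELS, _STAGE_LABELS].to_numpy()
    return StageCrossTab(counts, row_source=row_source, col_source=col_source)


def load_stage_crosstab(name: str) -> StageCrossTab:
    """Load one packaged published cross-tabulation by pair name."""
    if name not in STAGE_CROSSTAB_NAMES:
        raise KeyError(
            f"unknown crosstab {name!r}; available: {STAGE_CROSSTAB_NAMES}"
        )
    row_source, col_source = name.split("_vs_")
    with resources.files("spiroref.data").joinpath(
        f"stage_crosstab_{name}.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return _parse_crosstab(df, row_source, col_source)


def read_crosstab_file(path, row_source: str = "a", col_source: str = "b") -> StageCrossTab:
    """Read a user-supplied 4×4 count table in the same labelled TSV format."""
    return _parse_crosstab(pd.read_csv(path, sep="\t"), row_source, col_source)
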