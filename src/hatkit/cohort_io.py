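"""Cohort table I/O, schema validation, unit standardization, harmonization.

The on-disk format is a plain CSV, one row per participant, missing
values encoded as empty fields.  Schema (column -> constraint):

==================  =====================================================
participant_id      unique string
cohort              cohort label
age                 years (float)
sex                 ``female`` | ``male``
education           ``primary`` | ``high_school`` | ``university``
gait_speed          m/s, >= 0 (0 allowed for non-walkers) or missing
mmse                integer 0-30 or missing
n_chronic           integer 0-60 or missing
iadl                integer 0-8 or missing
padl                integer 0-6 or missing
death_time          years in (0, 16] (optional column)
death_event         0/1 (optional)
admit_1y, admit_3y  0/1 (optional)
admissions_unplanned 0/1 record-level provenance (optional)
gait_imputed        0/1 imputation provenance (optional)
==================  =====================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .synthetic_cohorts import INDICATORS, SEX_CODES, EDUCATION_CODES

__all__ = [
    "SchemaError",
    "HarmonizationReport",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_table",
    "standardize_units",
    "harmonize",
]

REQUIRED_COLUMNS = [
    "participant_id", "cohort", "age", "sex", "education",
    "gait_speed", "mmse", "n_chronic", "iadl", "padl",
]
OPTIONAL_COLUMNS = [
    "death_time", "death_event", "admit_1y", "admit_3y",
    "admissions_unplanned", "gait_imputed",
]
FOLLOWUP_HORIZON = 16.0

_INT_RANGES = {"mmse": (0, 30), "n_chronic": (0, 60), "iadl": (0, 8), "padl": (0, 6)}
_FLAG_COLUMNS = ["death_event", "admit_1y", "admit_3y", "admissions_unplanned", "gait_imputed"]


class SchemaError(ValueError):
    """Schema violation carrying row/column diagnostics."""


def _bad_rows(mask: pd.Series, col: str, what: str) -> SchemaError:
    rows = [int(i) for i in np.flatnonzero(mask.to_numpy())[:10]]
    return SchemaError(f"column {col!r}: {what} at row(s) {rows}")


def validate_table(table: pd.DataFrame, horizon: float = FOLLOWUP_HORIZON) -> None:
    """Raise :class:`SchemaError` on any schema violation; silent otherwise."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if table["participant_id"].duplicated().any():
        dups = table["participant_id"][table["participant_id"].duplicated()].head(5).tolist()
        raise SchemaError(f"duplicate participant_id(s): {dups}")
    bad = ~table["sex"].isin(SEX_CODES)
    if bad.any():
        raise _bad_rows(bad, "sex", "invalid code")
    bad = ~table["education"].isin(EDUCATION_CODES)
    if bad.any():
        raise _bad_rows(bad, "education", "invalid code")
    gait = pd.to_numeric(table["gait_speed"], errors="coerce")
    bad = table["gait_speed"].notna() & (gait.isna() | (gait < 0))
    if bad.any():
        raise _bad_rows(bad, "gait_speed", "negative or non-numeric")
    for col, (lo, hi) in _INT_RANGES.items():
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table[col].notna() & (vals.isna() | (vals < lo) | (vals > hi))
        if bad.any():
            raise _bad_rows(bad, col, f"outside [{lo}, {hi}]")
    if "death_time" in table.columns:
        dt = pd.to_numeric(table["death_time"], errors="coerce")
        bad = table["death_time"].notna() & (dt.isna() | (dt <= 0) | (dt > horizon))
        if bad.any():
            raise _bad_rows(bad, "death_time", f"outside (0, {horizon}]")
    for col in _FLAG_COLUMNS:
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="coerce")
            bad = table[col].notna() & ~vals.isin([0, 1])
            if bad.any():
                raise _bad_rows(bad, col, "flag not in {0, 1}")


def _schema_columns(table: pd.DataFrame) -> list[str]:
    return REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in table.columns]


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a validated table; internal columns (leading ``_``) are dropped."""
    validate_table(table)
    table[_schema_columns(table)].to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"participant_id": str, "cohort": str})
    validate_table(table)
    return table.reset_index(drop=True)


def standardize_units(table: pd.DataFrame) -> pd.DataFrame:
    """Resolve gait speed to m/s.

    If ``gait_distance_m``/``gait_time_s`` columns are present, rows with
    missing ``gait_speed`` are filled with distance/time; the raw pair
    columns are then dropped.  Already-standardized tables pass through
    unchanged (idempotent).
    """
    table = table.copy()
    if "gait_distance_m" in table.columns and "gait_time_s" in table.columns:
        dist = pd.to_numeric(table["gait_distance_m"], errors="coerce")
        tsec = pd.to_numeric(table["gait_time_s"], errors="coerce")
        bad = (dist > 0) & tsec.notna() & (tsec <= 0)
        if bad.any():
            raise _bad_rows(bad, "gait_time_s", "non-positive time with positive distance")
        fill = table["gait_speed"].isna() & dist.notna() & tsec.notna() & (tsec > 0)
        table.loc[fill, "gait_speed"] = (dist / tsec)[fill]
        table = table.drop(columns=["gait_distance_m", "gait_time_s"])
    return table


@dataclass
class HarmonizationReport:
    """Per-cohort accounting of the complete-case exclusion step."""

    baseline: dict[str, int] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)
    included: dict[str, int] = field(default_factory=dict)
    variables_checked: list[str] = field(default_factory=lambda: list(INDICATORS))
    impute_first: bool = False

    @property
    def total_included(self) -> int:
        return sum(self.included.values())

    @property
    def total_baseline(self) -> int:
        return sum(self.baseline.values())

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["total_baseline"] = self.total_baseline
        payload["total_included"] = self.total_included
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def harmonize(cohorts: list[pd.DataFrame], impute_first: bool = False
              ) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Concatenate cohorts after complete-case exclusion on the five indicators.

    Exclusion is *only* on the indicators; missing outcomes never
    exclude.  When ``impute_first`` is set the caller asserts that
    imputation has already filled the systematically missing indicator,
    so residual gait missingness in those cohorts still excludes.
    Output row order is (cohort name, participant_id), making the result
    invariant to the order of the input list.
    """
    for t in cohorts:
        validate_table(t)
    all_ids = pd.concat([t["participant_id"] for t in cohorts], ignore_index=True)
    if all_ids.duplicated().any():
        dups = all_ids[all_ids.duplicated()].head(5).tolist()
        raise SchemaError(f"participant ids overlap across cohorts: {dups}")

    report = HarmonizationReport(impute_first=impute_first)
    kept = []
    for t in sorted(cohorts, key=lambda t: str(t["cohort"].iloc[0])):
        name = str(t["cohort"].iloc[0])
        complete = t[list(INDICATORS)].notna().all(axis=1)
        report.baseline[name] = int(len(t))
        report.included[name] = int(complete.sum())
        report.excluded[name] = int((~complete).sum())
        kept.append(t[complete])
    merged = pd.concat(kept, ignore_index=True)
    merged = merged.sort_values(["cohort", "participant_id"]).reset_index(drop=True)
    return merged, report
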