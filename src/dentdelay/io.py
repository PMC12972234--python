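"""Cohort CSV reading, validation and writing.

Shared cohort schema (one row per child):
``id, sex, [group,] birth_date + exam_date OR ca_years,
stage_31..stage_37, stage_41..stage_47, cmt``
where stages are letters A-H (blank for congenitally missing teeth), dates
are ISO-8601, and ``cmt`` is a semicolon-separated list of FDI codes. When
both dates and ``ca_years`` are present, dates take precedence. The group
defaults to 'agenesis' when the CMT set is non-empty, else 'control'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .agenesis import InvalidToothError, validate_cmt_set
from .demirjian import chronological_age
from .tables import POSITIONS, STAGE_RANK

__all__ = ["ValidationReport", "CohortSchemaError", "read_cohort", "write_cohort"]

STAGE_COLS = [f"stage_3{p}" for p in POSITIONS] + [f"stage_4{p}" for p in POSITIONS]
REQUIRED_COLS = ["id", "sex"] + STAGE_COLS + ["cmt"]

#: Inclusion age window; chronological ages outside it are flagged, not fatal.
AGE_WINDOW = (6.0, 15.0)


class CohortSchemaError(ValueError):
    """The CSV does not carry the required cohort columns."""


@dataclass
class ValidationReport:
    """Row-level validation findings collected while reading a cohort."""

    errors: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        lines += [f"  row {i}: ERROR {m}" for i, m in self.errors]
        lines += [f"  row {i}: WARN  {m}" for i, m in self.warnings]
        return "\n".join(lines)


def read_cohort(path_or_buffer) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a cohort CSV.

    Returns the cohort as a DataFrame in the shared schema (invalid rows
    dropped) together with a :class:`ValidationReport` carrying per-row
    errors (unknown stages, invalid FDI codes, unusable ages) and warnings
    (ages outside the inclusion window). Raises :class:`CohortSchemaError`
    when required columns are absent.
    """
    df = pd.read_csv(path_or_buffer, dtype=str, comment="#").fillna("")
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort CSV is missing required columns {missing}")
    has_dates = "birth_date" in df.columns and "exam_date" in df.columns
    has_ca = "ca_years" in df.columns
    if not has_dates and not has_ca:
        raise CohortSchemaError(
            "cohort CSV needs either birth_date+exam_date or ca_years"
        )

    report = ValidationReport()
    rows = []
    for i, raw in df.iterrows():
        line = i + 2  # header is line 1
        ok = True
        row = {"id": str(raw["id"]).strip(), "sex": str(raw["sex"]).strip().lower()}
        if row["sex"] not in ("female", "male"):
            report.errors.append((line, f"unknown sex {raw['sex']!r}"))
            ok = False
        # chronological age
        ca = None
        if has_dates and raw.get("birth_date", "") and raw.get("exam_date", ""):
            try:
                ca = chronological_age(raw["birth_date"], raw["exam_date"])
            except ValueError as exc:
                report.errors.append((line, str(exc)))
                ok = False
        elif has_ca and str(raw.get("ca_years", "")).strip():
            try:
                ca = float(raw["ca_years"])
            except ValueError:
                report.errors.append((line, f"unparseable ca_years {raw['ca_years']!r}"))
                ok = False
        else:
            report.errors.append((line, "no usable chronological age"))
            ok = False
        if ca is not None and not AGE_WINDOW[0] <= ca <= AGE_WINDOW[1]:
            report.warnings.append(
                (line, f"chronological age {ca} outside inclusion window {AGE_WINDOW}")
            )
        row["ca_years"] = ca
        # CMT set
        cmt_raw = [c for c in str(raw["cmt"]).split(";") if c.strip()]
        try:
            cmt = validate_cmt_set(cmt_raw)
        except (InvalidToothError, ValueError) as exc:
            report.errors.append((line, str(exc)))
            ok = False
            cmt = frozenset()
        row["cmt"] = ";".join(str(c) for c in sorted(cmt))
        row["group"] = (
            str(raw["group"]).strip().lower()
            if "group" in df.columns and str(raw.get("group", "")).strip()
            else ("agenesis" if cmt else "control")
        )
        # stages
        for col in STAGE_COLS:
            stage = str(raw[col]).strip().upper()
            fdi = int(col.split("_")[1])
            if stage and stage not in STAGE_RANK:
                report.errors.append(
                    (line, f"invalid stage {raw[col]!r} for tooth {fdi}")
                )
                ok = False
                stage = ""
            if stage and fdi in cmt:
                report.errors.append(
                    (line, f"tooth {fdi} is staged but listed as congenitally missing")
                )
                ok = False
            row[col] = stage
        if ok:
            rows.append(row)
    cohort = pd.DataFrame(
        rows, columns=["id", "sex", "group", "ca_years"] + STAGE_COLS + ["cmt"]
    )
    return cohort, report


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort back to CSV (field-identical round trip for valid files)."""
    cohort.to_csv(path, index=False)
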