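"""Cohort tables and laboratory screening.

A cohort is a flat table of screened individuals: one row per subject with
an integer age in completed years (1-17), sex, a panel of serum analyte
activities (U/L), and an optional block of laboratory screening fields used
to exclude subjects that are not acceptable reference individuals
(elevated creatinine, CRP, positive serology, ...).

CSV dialect: comma-separated, UTF-8, header row required, "." decimal mark.
Reading is collect-and-report: malformed rows are returned as structured
errors alongside the successfully parsed records, never raised mid-file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SubjectRecord",
    "RowError",
    "CohortReadResult",
    "ExclusionCriteria",
    "read_cohort",
    "write_cohort",
    "apply_exclusion",
    "SCREENING_NUMERIC_FIELDS",
    "SEROLOGY_FIELDS",
]

AGE_MIN = 1
AGE_MAX = 17

#: numeric screening fields, with their units (documentation only)
SCREENING_NUMERIC_FIELDS: tuple[str, ...] = (
    "creatinine",  # µmol/L
    "uric_acid",   # µmol/L
    "glucose",     # mmol/L
    "albumin",     # g/L
    "crp",         # mg/L
    "ck",          # U/L
    "hemoglobin",  # g/L
    "wbc",         # 10^9/L
)

#: serology flags; truthy value = positive
SEROLOGY_FIELDS: tuple[str, ...] = ("hbsag", "hcv", "hiv")

_SCREENING_FIELDS = SCREENING_NUMERIC_FIELDS + SEROLOGY_FIELDS
_REQUIRED_COLUMNS = ("subject_id", "age_years", "sex")
_FLAGS_COLUMN = "flags"

_TRUTHY = {"1", "true", "yes", "pos", "positive", "+"}
_FALSY = {"0", "false", "no", "neg", "negative", "-", ""}


@dataclass(frozen=True)
class SubjectRecord:
    """One screened individual.

    ``analytes`` maps analyte name to measured activity (U/L, >= 0).
    ``screening`` holds the optional laboratory-screening block; missing
    fields simply stay absent. ``detection_flags`` names the analytes whose
    value was reported at the assay's lower detection limit (censored from
    below). ``extras`` preserves unknown CSV columns verbatim.
    """

    subject_id: str
    age_years: int
    sex: str
    analytes: Mapping[str, float]
    screening: Mapping[str, float | bool] = field(default_factory=dict)
    detection_flags: frozenset[str] = frozenset()
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not (AGE_MIN <= self.age_years <= AGE_MAX):
            raise ValueError(
                f"age out of range: {self.age_years} not in [{AGE_MIN}, {AGE_MAX}]"
            )
        for name, value in self.analytes.items():
            if value < 0:
                raise ValueError(f"analyte {name} negative: {value}")


@dataclass(frozen=True)
class RowError:
    """A rejected CSV row: 1-based data row number and the reason."""

    row: int
    reason: str


@dataclass(frozen=True)
class CohortReadResult:
    records: list[SubjectRecord]
    errors: list[RowError]


@dataclass(frozen=True)
class ExclusionCriteria:
    """Laboratory exclusion thresholds for reference individuals.

    All comparisons are strict inequalities; a value exactly at a threshold
    is kept.  Sex-specific thresholds (creatinine, hemoglobin) are applied
    only to the matching sex; the WBC rule is two-sided.  A record missing a
    screening field is never excluded on that field.
    """

    creatinine_m_gt: float = 97.0    # µmol/L
    creatinine_f_gt: float = 73.0    # µmol/L
    uric_acid_gt: float = 475.0      # µmol/L
    glucose_gt: float = 7.0          # mmol/L
    albumin_lt: float = 35.0         # g/L
    crp_gt: float = 10.0             # mg/L
    ck_gt: float = 500.0             # U/L
    hemoglobin_m_lt: float = 120.0   # g/L
    hemoglobin_f_lt: float = 110.0   # g/L
    wbc_lt: float = 3.0              # 10^9/L
    wbc_gt: float = 12.0             # 10^9/L
    exclude_serology: bool = True


def _parse_bool(text: str) -> bool:
    low = text.strip().lower()
    if low in _TRUTHY:
        return True
    if low in _FALSY:
        return False
    raise ValueError(f"unparsable flag value {text!r}")


def read_cohort(path) -> CohortReadResult:
    """Read a cohort CSV into typed records.

    Columns beyond subject_id/age_years/sex are classified by name: known
    screening fields go to ``screening``, the ``flags`` column restores
    detection flags, any numeric leftover is an analyte, and non-numeric
    leftovers are preserved as opaque extras.  Bad rows become RowErrors
    carrying the 1-based data row number.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        header = [h.strip() for h in reader.fieldnames]
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
        other_cols = [c for c in header if c not in _REQUIRED_COLUMNS]

        records: list[SubjectRecord] = []
        errors: list[RowError] = []
        for row_no, row in enumerate(reader, start=1):
            try:
                records.append(_parse_row(row, other_cols))
            except ValueError as exc:
                errors.append(RowError(row=row_no, reason=str(exc)))
    return CohortReadResult(records=records, errors=errors)


def _parse_row(row: Mapping[str, str], other_cols: Sequence[str]) -> SubjectRecord:
    try:
        age = int(str(row["age_years"]).strip())
    except (TypeError, ValueError):
        raise ValueError(f"unparsable age {row.get('age_years')!r}")
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError("age out of range")
    sex = str(row.get("sex", "")).strip().upper()
    if sex not in ("M", "F"):
        raise ValueError(f"unparsable sex {row.get('sex')!r}")

    analytes: dict[str, float] = {}
    screening: dict[str, float | bool] = {}
    extras: dict[str, str] = {}
    flags: frozenset[str] = frozenset()
    for col in other_cols:
        raw = row.get(col)
        if raw is None or str(raw).strip() == "":
            continue
        raw = str(raw).strip()
        if col == _FLAGS_COLUMN:
            flags = frozenset(f for f in raw.split(";") if f)
        elif col in SEROLOGY_FIELDS:
            screening[col] = _parse_bool(raw)
        elif col in SCREENING_NUMERIC_FIELDS:
            screening[col] = float(raw)
        else:
            try:
                analytes[col] = float(raw)
            except ValueError:
                extras[col] = raw

    return SubjectRecord(
        subject_id=str(row["subject_id"]).strip(),
        age_years=age,
        sex=sex,
        analytes=analytes,
        screening=screening,
        detection_flags=flags,
        extras=extras,
    )


def write_cohort(records: Iterable[SubjectRecord], path) -> None:
    """Write records as a cohort CSV (round-trips through read_cohort)."""
    records = list(records)
    analyte_cols: list[str] = []
    screening_cols: list[str] = []
    extra_cols: list[str] = []
    for rec in records:
        for name in rec.analytes:
            if name not in analyte_cols:
                analyte_cols.append(name)
        for name in rec.extras:
            if name not in extra_cols:
                extra_cols.append(name)
    for name in _SCREENING_FIELDS:
        if any(name in rec.screening for rec in records):
            screening_cols.append(name)

    header = list(_REQUIRED_COLUMNS) + analyte_cols + screening_cols + extra_cols + [_FLAGS_COLUMN]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row: list[str] = [rec.subject_id, str(rec.age_years), rec.sex]
            for col in analyte_cols:
                value = rec.analytes.get(col)
                row.append("" if value is None else repr(float(value)))
            for col in screening_cols:
                value = rec.screening.get(col)
                if value is None:
                    row.append("")
                elif col in SEROLOGY_FIELDS:
                    row.append("1" if value else "0")
                else:
                    row.append(repr(float(value)))
            for col in extra_cols:
                row.append(rec.extras.get(col, ""))
            row.append(";".join(sorted(rec.detection_flags)))
            writer.writerow(row)


def _screening_value(rec: SubjectRecord, name: str):
    """Screening field lookup; CK falls back to the measured analyte."""
    value = rec.screening.get(name)
    if value is None and name == "ck":
        value = rec.analytes.get("CK", rec.analytes.get("ck"))
    return value


def exclusion_reasons(rec: SubjectRecord, criteria: ExclusionCriteria) -> tuple[str, ...]:
    """All exclusion reason codes firing for one record (empty = kept)."""
    reasons: list[str] = []
    if criteria.exclude_serology:
        for name in SEROLOGY_FIELDS:
            if rec.screening.get(name):
                reasons.append(f"{name.upper()}+")

    crea = _screening_value(rec, "creatinine")
    if crea is not None:
        if rec.sex == "M" and crea > criteria.creatinine_m_gt:
            reasons.append(f"creatinine>{criteria.creatinine_m_gt:g}(M)")
        elif rec.sex == "F" and crea > criteria.creatinine_f_gt:
            reasons.append(f"creatinine>{criteria.creatinine_f_gt:g}(F)")

    ua = _screening_value(rec, "uric_acid")
    if ua is not None and ua > criteria.uric_acid_gt:
        reasons.append(f"uric_acid>{criteria.uric_acid_gt:g}")
    glu = _screening_value(rec, "glucose")
    if glu is not None and glu > criteria.glucose_gt:
        reasons.append(f"glucose>{criteria.glucose_gt:g}")
    alb = _screening_value(rec, "albumin")
    if alb is not None and alb < criteria.albumin_lt:
        reasons.append(f"albumin<{criteria.albumin_lt:g}")
    crp = _screening_value(rec, "crp")
    if crp is not None and crp > criteria.crp_gt:
        reasons.append(f"CRP>{criteria.crp_gt:g}")
    ck = _screening_value(rec, "ck")
    if ck is not None and ck > criteria.ck_gt:
        reasons.append(f"CK>{criteria.ck_gt:g}")

    hgb = _screening_value(rec, "hemoglobin")
    if hgb is not None:
        if rec.sex == "M" and hgb < criteria.hemoglobin_m_lt:
            reasons.append(f"hemoglobin<{criteria.hemoglobin_m_lt:g}(M)")
        elif rec.sex == "F" and hgb < criteria.hemoglobin_f_lt:
            reasons.append(f"hemoglobin<{criteria.hemoglobin_f_lt:g}(F)")

    wbc = _screening_value(rec, "wbc")
    if wbc is not None:
        if wbc < criteria.wbc_lt:
            reasons.append(f"WBC<{criteria.wbc_lt:g}")
        elif wbc > criteria.wbc_gt:
            reasons.append(f"WBC>{criteria.wbc_gt:g}")

    return tuple(reasons)


def apply_exclusion(
    records: Iterable[SubjectRecord],
    criteria: ExclusionCriteria | None = None,
) -> tuple[list[SubjectRecord], list[tuple[SubjectRecord, tuple[str, ...]]]]:
    """Partition records into (kept, excluded-with-reason-codes).

    A record is excluded iff at least one criterion fires; the excluded list
    carries every firing reason.  Records missing a screening field pass on
    that field by design.
    """
    if criteria is None:
        criteria = ExclusionCriteria()
    kept: list[SubjectRecord] = []
    excluded: list[tuple[SubjectRecord, tuple[str, ...]]] = []
    for rec in records:
        reasons = exclusion_reasons(rec, criteria)
        if reasons:
            excluded.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, excluded
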