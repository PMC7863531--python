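"""Data model and CSV I/O for shelter intake/outcome records.

The canonical raw record carries the nine variables tracked for every
animal entering a shelter: species (dog/cat), breed, color, gender, age,
intake and outcome dates, outcome type (adopted / returned to owner /
euthanized) and the shelter location that housed the animal.  Source
portals disagree on headers and label spellings, so everything is funnelled
through one internal schema (comma-separated, UTF-8, ISO-8601 dates) with a
case-insensitive synonym table for the closed vocabularies.

Reading never silently drops a data row: every cell that cannot be parsed
becomes a missing value plus a :class:`ValidationIssue`, and the only rows
removed at this stage are species outside the dog/cat focus (each recorded
as an issue as well), so ``rows_in == records_out + dropped_rows``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("shelterops")

# Canonical raw CSV header, in order.
RAW_COLUMNS = (
    "animal_id",
    "type",
    "breed",
    "color",
    "gender",
    "age_years",
    "intake_date",
    "outcome_date",
    "outcome_type",
    "location",
)

ANIMAL_TYPES = ("dog", "cat")
GENDERS = ("male", "female")
OUTCOME_TYPES = ("adopted", "returned", "euthanized")

# Case-insensitive label harmonisation for multi-source data.
_TYPE_SYNONYMS = {"dog": "dog", "canine": "dog", "cat": "cat", "feline": "cat"}
_GENDER_SYNONYMS = {
    "male": "male", "m": "male",
    "female": "female", "f": "female",
    "neutered male": "male", "spayed female": "female",
    "intact male": "male", "intact female": "female",
}
_OUTCOME_SYNONYMS = {
    "adopted": "adopted", "adoption": "adopted", "adopt": "adopted",
    "returned": "returned", "return": "returned",
    "return to owner": "returned", "returned to owner": "returned",
    "rto": "returned",
    "euthanized": "euthanized", "euthanasia": "euthanized",
    "euthanize": "euthanized", "put to sleep": "euthanized",
}

# Species that may appear in multi-species portals but are out of scope.
_OTHER_SPECIES = {"bird", "rabbit", "lizard", "other", "livestock", "guinea pig"}


class SchemaError(ValueError):
    """Fatal raw-CSV schema problem (missing header, empty file)."""


@dataclass
class AnimalRecord:
    """One raw intake/outcome row.

    Unparseable or absent cells are ``None``; ``valid`` is False when the
    record carries an internally inconsistent date pair (outcome before
    intake), which downstream cleaning treats as erroneous.
    """

    animal_id: str
    animal_type: str | None
    breed_raw: str | None
    color_raw: str | None
    gender: str | None
    age_years: float | None
    intake_date: date | None
    outcome_date: date | None
    outcome_type: str | None
    location: str | None
    valid: bool = True


@dataclass
class ValidationIssue:
    row_index: int
    field: str
    kind: str  # missing | out_of_range | unparseable | negative_stay
    detail: str = ""


@dataclass
class ProcessedRecord:
    """Model-ready record: every predictor binned to its closed vocabulary.

    ``days_in_shelter`` is the categorisation input (returned animals are
    zeroed, everything capped at 365); ``raw_days`` keeps the uncapped,
    un-zeroed stay for reporting.  ``age_category``/``location`` may be
    ``None`` only under the unique-value cleaning strategies, where the
    sentinel code means "outside every known category" and one-hot encodes
    to an all-zeros block.
    """

    animal_type: str
    size_category: str
    color_category: str
    gender: str
    age_category: str | None
    location: str | None
    outcome_type: str
    days_in_shelter: int
    los_class: str
    raw_days: int

    _COLUMNS = (
        "animal_type", "size_category", "color_category", "gender",
        "age_category", "location", "outcome_type", "days_in_shelter",
        "los_class", "raw_days",
    )


def _norm_token(raw: str | None) -> str | None:
    if raw is None:
        return None
    s = str(raw).strip().lower()
    return s or None


def _parse_date(raw: str | None) -> date | None:
    if raw is None or str(raw).strip() == "":
        return None
    return date.fromisoformat(str(raw).strip())


def read_records(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[AnimalRecord], list[ValidationIssue]]:
    """Read a raw CSV into records plus a validation-issue report.

    Parameters
    ----------
    path:
        CSV file with a header row.
    column_map:
        Optional mapping from source headers to the canonical column names
        in :data:`RAW_COLUMNS`, for portals with their own dialects.

    Returns
    -------
    (records, issues):
        One record per dog/cat data row.  Rows for other species are
        dropped, with an issue each; no other row is removed here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[AnimalRecord] = []
    issues: list[ValidationIssue] = []

    for i, row in enumerate(df.itertuples(index=False)):
        raw = {c: getattr(row, c, None) for c in RAW_COLUMNS}
        raw = {k: (None if v is None or str(v).strip() == "" else str(v).strip())
               for k, v in raw.items()}

        tok = _norm_token(raw["type"])
        animal_type = _TYPE_SYNONYMS.get(tok) if tok else None
        if tok and animal_type is None:
            # Out-of-scope species: the study covers dogs and cats only.
            issues.append(ValidationIssue(i, "type", "out_of_range",
                                          f"species {tok!r} not in scope; row dropped"))
            continue
        if animal_type is None:
            issues.append(ValidationIssue(i, "type", "missing"))

        gender = None
        tok = _norm_token(raw["gender"])
        if tok is None:
            issues.append(ValidationIssue(i, "gender", "missing"))
        elif tok in _GENDER_SYNONYMS:
            gender = _GENDER_SYNONYMS[tok]
        else:
            issues.append(ValidationIssue(i, "gender", "unparseable", tok))

        outcome = None
        tok = _norm_token(raw["outcome_type"])
        if tok is None:
            issues.append(ValidationIssue(i, "outcome_type", "missing"))
        elif tok in _OUTCOME_SYNONYMS:
            outcome = _OUTCOME_SYNONYMS[tok]
        else:
            issues.append(ValidationIssue(i, "outcome_type", "unparseable", tok))

        age: float | None = None
        if raw["age_years"] is None:
            issues.append(ValidationIssue(i, "age_years", "missing"))
        else:
            try:
                age = float(raw["age_years"])
            except ValueError:
                issues.append(ValidationIssue(i, "age_years", "unparseable",
                                              raw["age_years"]))
            else:
                if age < 0:
                    issues.append(ValidationIssue(i, "age_years", "out_of_range",
                                                  f"negative age {age}"))
                    age = None

        dates: dict[str, date | None] = {}
        for col in ("intake_date", "outcome_date"):
            try:
                dates[col] = _parse_date(raw[col])
            except ValueError:
                dates[col] = None
                issues.append(ValidationIssue(i, col, "unparseable", raw[col] or ""))
        if raw["intake_date"] is None:
            issues.append(ValidationIssue(i, "intake_date", "missing"))

        if raw["color"] is None:
            issues.append(ValidationIssue(i, "color", "missing"))
        if raw["breed"] is None:
            issues.append(ValidationIssue(i, "breed", "missing"))

        valid = True
        if (dates["intake_date"] is not None and dates["outcome_date"] is not None
                and dates["outcome_date"] < dates["intake_date"]):
            valid = False
            issues.append(ValidationIssue(
                i, "outcome_date", "negative_stay",
                f"outcome {dates['outcome_date']} before intake {dates['intake_date']}"))

        records.append(AnimalRecord(
            animal_id=raw["animal_id"] or f"row{i}",
            animal_type=animal_type,
            breed_raw=raw["breed"],
            color_raw=raw["color"],
            gender=gender,
            age_years=age,
            intake_date=dates["intake_date"],
            outcome_date=dates["outcome_date"],
            outcome_type=outcome,
            location=raw["location"],
            valid=valid,
        ))
    return records, issues


def write_records(records: Sequence[AnimalRecord], path: str | Path) -> None:
    """Write raw records in the canonical CSV dialect."""
    if not records:
        raise ValueError("refusing to write an empty record list")
    rows = []
    for r in records:
        rows.append({
            "animal_id": r.animal_id,
            "type": r.animal_type or "",
            "breed": r.breed_raw or "",
            "color": r.color_raw or "",
            "gender": r.gender or "",
            "age_years": "" if r.age_years is None else repr(float(r.age_years)),
            "intake_date": r.intake_date.isoformat() if r.intake_date else "",
            "outcome_date": r.outcome_date.isoformat() if r.outcome_date else "",
            "outcome_type": r.outcome_type or "",
            "location": r.location or "",
        })
    pd.DataFrame(rows, columns=list(RAW_COLUMNS)).to_csv(path, index=False)


def write_processed(records: Sequence[ProcessedRecord], path: str | Path) -> None:
    """Write processed records; round-trips exactly through read_processed."""
    if not records:
        raise ValueError("refusing to write an empty record list")
    rows = [{c: getattr(r, c) for c in ProcessedRecord._COLUMNS} for r in records]
    df = pd.DataFrame(rows, columns=list(ProcessedRecord._COLUMNS))
    df.to_csv(path, index=False)


def read_processed(path: str | Path) -> list[ProcessedRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ProcessedRecord._COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing processed column(s): {', '.join(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = {c: getattr(row, c) for c in ProcessedRecord._COLUMNS}
        d["days_in_shelter"] = int(d["days_in_shelter"])
        d["raw_days"] = int(d["raw_days"])
        d["age_category"] = d["age_category"] or None
        d["location"] = d["location"] or None
        out.append(ProcessedRecord(**d))
    return out


def write_issues(issues: Iterable[ValidationIssue], path: str | Path) -> None:
    """Sidecar CSV report of validation issues."""
    rows = [{"row_index": iss.row_index, "field": iss.field,
             "kind": iss.kind, "detail": iss.detail} for iss in issues]
    pd.DataFrame(rows, columns=["row_index", "field", "kind", "detail"]).to_csv(
        path, index=False)
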