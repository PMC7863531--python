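"""Cleaning strategies and categorical binning for shelter records.

Turns raw intake/outcome rows into model-ready records:

* stay in days = outcome date − intake date, capped at 365 (longer stays
  are special cases; negative differences are erroneous, never clamped);
* the target, length of stay (LOS), discretised to four classes — ``low``
  (returned to owner, forced to 0 days, or adopted within 8 days),
  ``medium`` (adopted after 9–42 days), ``high`` (adopted after 43–365
  days) and ``very_high`` (euthanized, regardless of days);
* age binned to puppy/kitten [0,1], adolescent (1,3], adult (3,7],
  senior (7,10] and super senior (>10) years — half-open so fractional
  ages land in exactly one bin;
* breed reduced to its first listed component, looked up in an editable
  breed→size table (AKC-style small/medium/large, unknown → "other" →
  medium);
* color reduced to five categories (brown, black, blue, white,
  multicolor); any multi-token color is multicolor.

Five cleaning strategies are supported: median (mode for nominal fields)
substitution, unique-value (−1) substitution, both again after discarding
variables with too many missing values, and whole-row removal.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import AnimalRecord, ProcessedRecord, ValidationIssue

logger = logging.getLogger("shelterops")

MAX_DAYS = 365

SIZE_CATEGORIES = ("small", "medium", "large")
COLOR_CATEGORIES = ("brown", "black", "blue", "white", "multicolor")
AGE_CATEGORIES = ("puppy_kitten", "adolescent", "adult", "senior", "super_senior")
LOS_CLASSES = ("low", "medium", "high", "very_high")

CLEANING_STRATEGIES = (
    "substitute_median",
    "substitute_unique",
    "discard_var_then_median",
    "discard_var_then_unique",
    "remove_rows",
)

UNIQUE_CODE = -1  # out-of-range code used by the unique-value strategies


class NegativeStayError(ValueError):
    """Outcome date precedes intake date: erroneous record, not clamped."""


def _load_two_column_csv(name: str) -> dict[str, str]:
    with resources.files("shelterops.data").joinpath(name).open() as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        return {k.strip().lower(): v.strip().lower() for k, v in reader}


def load_breed_size_map(path: str | Path | None = None) -> dict[str, str]:
    """Bundled (or user-supplied) breed→size lookup table."""
    if path is None:
        return _load_two_column_csv("breed_size_map.csv")
    with open(path) as fh:
        reader = csv.reader(fh)
        next(reader)
        return {k.strip().lower(): v.strip().lower() for k, v in reader}


def load_color_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Bundled (or user-supplied) color-token→category lookup table."""
    if path is None:
        return _load_two_column_csv("color_synonyms.csv")
    with open(path) as fh:
        reader = csv.reader(fh)
        next(reader)
        return {k.strip().lower(): v.strip().lower() for k, v in reader}


# ---------------------------------------------------------------------------
# Binning rules
# ---------------------------------------------------------------------------

def compute_days(intake_date: date, outcome_date: date) -> int:
    """Whole days between intake and outcome, capped at 365.

    Raises :class:`NegativeStayError` for a negative difference — such
    records are erroneous and must be handled by the cleaner, not clamped.
    """
    delta = (outcome_date - intake_date).days
    if delta < 0:
        raise NegativeStayError(
            f"outcome {outcome_date} precedes intake {intake_date}")
    return min(delta, MAX_DAYS)


def classify_los(days: int, outcome_type: str) -> str:
    """Four-class LOS label.

    Euthanized animals are ``very_high`` regardless of stay; returned
    animals are ``low`` (their stay is recorded as 0 — the shelter holds
    them for owner pickup); adopted animals split at 8 and 42 days.
    """
    if outcome_type == "euthanized":
        return "very_high"
    if outcome_type == "returned":
        return "low"
    if outcome_type != "adopted":
        raise ValueError(f"unknown outcome type {outcome_type!r}")
    if not 0 <= days <= MAX_DAYS:
        raise ValueError(f"days {days} outside [0, {MAX_DAYS}]")
    if days <= 8:
        return "low"
    if days <= 42:
        return "medium"
    return "high"


def classify_age(age_years: float) -> str:
    """Five age bins: [0,1], (1,3], (3,7], (7,10], (10,inf)."""
    if age_years < 0:
        raise ValueError(f"negative age {age_years}")
    if age_years <= 1:
        return "puppy_kitten"
    if age_years <= 3:
        return "adolescent"
    if age_years <= 7:
        return "adult"
    if age_years <= 10:
        return "senior"
    return "super_senior"


def normalize_breed(breed_raw: str, known_breeds: Iterable[str] | None = None) -> str:
    """Case-folded first listed breed; unknown breeds collapse to "other".

    Multi-breed strings like ``"Shih Tzu/Yorkshire Terr"`` or
    ``"Shih Tzu/mix"`` keep only the first component; a trailing " mix"
    marker is stripped.  When ``known_breeds`` is given, any breed outside
    it becomes ``"other"``.
    """
    if not breed_raw or not breed_raw.strip():
        raise ValueError("empty breed string")
    first = breed_raw.split("/")[0].strip().lower()
    if first.endswith(" mix"):
        first = first[:-4].strip()
    if first in ("mix", "mixed", ""):
        first = "other"
    if known_breeds is not None and first != "other" and first not in set(known_breeds):
        return "other"
    return first


def classify_size(canonical_breed: str, mapping: Mapping[str, str] | None = None) -> str:
    """Breed→size lookup; "other" and unmapped breeds default to medium."""
    if mapping is None:
        mapping = load_breed_size_map()
    return mapping.get(canonical_breed, "medium")


def _color_tokens(color_raw: str) -> list[str]:
    s = color_raw.lower().replace("&", " ").replace(",", " ").replace("/", " ")
    s = s.replace(" and ", " ")
    return [t for t in s.split() if t]


def classify_color(
    color_raw: str,
    synonyms: Mapping[str, str] | None = None,
    default: str = "brown",
    issues: list[ValidationIssue] | None = None,
    row_index: int = -1,
) -> str:
    """Map a raw color string onto the five color categories.

    Any string naming two or more colors (``"black/white"``) is
    multicolor; a single known token maps through the synonym table; an
    unknown single token falls back to ``default`` and is logged.
    """
    if not color_raw or not color_raw.strip():
        raise ValueError("empty color string")
    if synonyms is None:
        synonyms = load_color_synonyms()
    if "/" in color_raw:
        return "multicolor"
    tokens = _color_tokens(color_raw)
    known = [t for t in tokens if t in synonyms]
    if len(known) >= 2:
        return "multicolor"
    if len(known) == 1:
        return synonyms[known[0]]
    if issues is not None:
        issues.append(ValidationIssue(row_index, "color", "unparseable",
                                      f"unknown color {color_raw!r}; defaulted to {default}"))
    else:
        logger.debug("unknown color %r defaulted to %s", color_raw, default)
    return default


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

@dataclass
class CleaningReport:
    strategy: str
    n_input: int = 0
    n_imputed: int = 0      # rows with at least one imputed/coded cell
    n_removed: int = 0
    n_output: int = 0
    imputed_by_field: dict = field(default_factory=dict)
    discarded_variables: list = field(default_factory=list)


def clean_frame(
    df: pd.DataFrame,
    strategy: str,
    numeric_cols: Sequence[str],
    categorical_cols: Sequence[str],
    discard_threshold: float = 0.5,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply one of the five cleaning techniques to a tabular frame.

    Missing cells are NaN/None.  Median substitution uses the column
    median for numeric variables and the mode for nominal ones (a median
    is meaningless on nominal data); unique-value substitution codes
    missing cells as −1 (the string ``"-1"`` for nominal columns).  The
    discard variants first drop any column whose missing fraction exceeds
    ``discard_threshold``.  ``remove_rows`` drops every row with a missing
    cell.  Always ``n_input == n_output + n_removed``.
    """
    if strategy not in CLEANING_STRATEGIES:
        raise ValueError(f"unknown cleaning strategy {strategy!r}")
    df = df.copy()
    report = CleaningReport(strategy=strategy, n_input=len(df))

    if strategy in ("discard_var_then_median", "discard_var_then_unique"):
        frac = df[list(numeric_cols) + list(categorical_cols)].isna().mean()
        drop = [c for c in frac.index if frac[c] > discard_threshold]
        df = df.drop(columns=drop)
        report.discarded_variables = drop
        numeric_cols = [c for c in numeric_cols if c not in drop]
        categorical_cols = [c for c in categorical_cols if c not in drop]

    cols = list(numeric_cols) + list(categorical_cols)
    if strategy == "remove_rows":
        keep = ~df[cols].isna().any(axis=1)
        report.n_removed = int((~keep).sum())
        df = df[keep]
    else:
        imputed_rows = df[cols].isna().any(axis=1)
        report.n_imputed = int(imputed_rows.sum())
        for c in cols:
            n_missing = int(df[c].isna().sum())
            if n_missing == 0:
                continue
            report.imputed_by_field[c] = n_missing
            if strategy.endswith("median"):
                if c in numeric_cols:
                    fill = df[c].median()
                else:
                    fill = df[c].mode(dropna=True)
                    fill = fill.iloc[0] if len(fill) else "-1"
            else:  # unique-value coding
                fill = UNIQUE_CODE if c in numeric_cols else str(UNIQUE_CODE)
            df[c] = df[c].fillna(fill)

    report.n_output = len(df)
    return df, report


# ---------------------------------------------------------------------------
# Record pipeline
# ---------------------------------------------------------------------------

def _records_to_frame(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Raw records → working frame with a computed stay column.

    ``days`` is NaN when a date is missing or the stay is negative; the
    ``negative_stay`` flag distinguishes the erroneous case.
    """
    rows = []
    for r in records:
        days = np.nan
        negative = False
        if r.intake_date is not None and r.outcome_date is not None:
            if not r.valid or r.outcome_date < r.intake_date:
                negative = True
            else:
                days = compute_days(r.intake_date, r.outcome_date)
        rows.append({
            "animal_id": r.animal_id,
            "animal_type": r.animal_type,
            "breed": r.breed_raw,
            "color": r.color_raw,
            "gender": r.gender,
            "age_years": r.age_years,
            "location": r.location,
            "outcome_type": r.outcome_type,
            "days": days,
            "negative_stay": negative,
        })
    return pd.DataFrame(rows)


def process_records(
    records: Sequence[AnimalRecord],
    strategy: str = "remove_rows",
    breed_size_map: Mapping[str, str] | None = None,
    color_synonyms: Mapping[str, str] | None = None,
    discard_threshold: float = 0.5,
    color_default: str = "brown",
) -> tuple[list[ProcessedRecord], CleaningReport]:
    """Full cleaning + binning pipeline.

    The target ingredients (dates, outcome type) and the closed-vocabulary
    fields species and gender can never be fabricated by imputation, so
    rows missing any of them — and rows with a negative stay — are removed
    under every strategy.  The chosen strategy governs the predictor
    fields breed, color, age and location.  Under the unique-value
    strategies the −1 code for age/location survives as ``None`` in the
    processed record (no known bin), which one-hot encodes to an all-zeros
    block.
    """
    if strategy not in CLEANING_STRATEGIES:
        raise ValueError(f"unknown cleaning strategy {strategy!r}")
    if breed_size_map is None:
        breed_size_map = load_breed_size_map()
    if color_synonyms is None:
        color_synonyms = load_color_synonyms()

    df = _records_to_frame(records)
    report = CleaningReport(strategy=strategy, n_input=len(df))
    if len(df) == 0:
        return [], report

    # Mandatory fields: erroneous/missing -> row removed under any strategy.
    mandatory_ok = (
        df["animal_type"].notna() & df["gender"].notna()
        & df["outcome_type"].notna() & df["days"].notna()
        & ~df["negative_stay"]
    )
    removed = int((~mandatory_ok).sum())
    df = df[mandatory_ok]

    predictor_cols = ["breed", "color", "age_years", "location"]
    sub = df[predictor_cols + ["animal_type", "gender", "outcome_type", "days",
                               "animal_id"]]
    cleaned, inner = clean_frame(
        sub, strategy, numeric_cols=["age_years"],
        categorical_cols=["breed", "color", "location"],
        discard_threshold=discard_threshold,
    )
    report.n_removed = removed + inner.n_removed
    report.n_imputed = inner.n_imputed
    report.imputed_by_field = inner.imputed_by_field
    report.discarded_variables = inner.discarded_variables

    issues: list[ValidationIssue] = []
    out: list[ProcessedRecord] = []
    for row in cleaned.itertuples(index=True):
        breed_raw = getattr(row, "breed", None)
        if breed_raw is None or breed_raw == str(UNIQUE_CODE):
            size = "medium"  # unknown breed -> "other" -> medium
        else:
            canonical = normalize_breed(str(breed_raw), known_breeds=breed_size_map)
            size = classify_size(canonical, breed_size_map)

        color_raw = getattr(row, "color", None)
        if color_raw is None or color_raw == str(UNIQUE_CODE):
            color = color_default
        else:
            color = classify_color(str(color_raw), color_synonyms,
                                   default=color_default, issues=issues,
                                   row_index=row.Index)

        age = getattr(row, "age_years", None)
        if age is None or (isinstance(age, float) and np.isnan(age)):
            age_cat: str | None = None
        elif age == UNIQUE_CODE:
            age_cat = None  # unique code: outside every known bin
        else:
            age_cat = classify_age(float(age))

        loc = getattr(row, "location", None)
        location = None if (loc is None or loc == str(UNIQUE_CODE)) else str(loc)

        raw_days = int(row.days)
        days = 0 if row.outcome_type == "returned" else min(raw_days, MAX_DAYS)
        los = classify_los(days, row.outcome_type)

        out.append(ProcessedRecord(
            animal_type=row.animal_type,
            size_category=size,
            color_category=color,
            gender=row.gender,
            age_category=age_cat,
            location=location,
            outcome_type=row.outcome_type,
            days_in_shelter=days,
            los_class=los,
            raw_days=raw_days,
        ))

    report.n_output = len(out)
    if issues:
        logger.info("%d color cell(s) defaulted to %s", len(issues), color_default)
    return out, report


# ---------------------------------------------------------------------------
# Feature encoding
# ---------------------------------------------------------------------------

FEATURE_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "animal_type": ("dog", "cat"),
    "size_category": SIZE_CATEGORIES,
    "color_category": COLOR_CATEGORIES,
    "gender": ("male", "female"),
    "age_category": AGE_CATEGORIES,
}


@dataclass
class FeatureManifest:
    """Deterministic one-hot layout: ordered (feature, category) columns.

    Persisted with the fitted model so the exact same layout is reused at
    prediction time; a category unseen in the manifest encodes to an
    all-zeros block for its feature.
    """

    columns: list[tuple[str, str]]

    @property
    def names(self) -> list[str]:
        return [f"{feat}={cat}" for feat, cat in self.columns]

    def __len__(self) -> int:
        return len(self.columns)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"columns": self.columns}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureManifest":
        data = json.loads(Path(path).read_text())
        return cls(columns=[tuple(c) for c in data["columns"]])


def build_manifest(records: Sequence[ProcessedRecord]) -> FeatureManifest:
    """Manifest over the fixed vocabularies plus observed locations (sorted)."""
    columns: list[tuple[str, str]] = []
    for feat, vocab in FEATURE_VOCABULARIES.items():
        columns.extend((feat, cat) for cat in vocab)
    locations = sorted({r.location for r in records if r.location is not None})
    columns.extend(("location", loc) for loc in locations)
    return FeatureManifest(columns=columns)


def encode_features(
    records: Sequence[ProcessedRecord] | ProcessedRecord,
    manifest: FeatureManifest,
) -> np.ndarray:
    """One-hot encode records against a manifest.

    Returns a (n, len(manifest)) float array (1-d for a single record).
    Exactly one 1 per categorical block, except blocks whose value is
    unknown/None, which are all zeros (warning logged once per feature).
    """
    single = isinstance(records, ProcessedRecord)
    recs = [records] if single else list(records)
    index = {col: j for j, col in enumerate(manifest.columns)}
    known_features = {feat for feat, _ in manifest.columns}
    X = np.zeros((len(recs), len(manifest.columns)))
    warned: set[tuple[str, str]] = set()
    for i, r in enumerate(recs):
        for feat in known_features:
            val = getattr(r, feat)
            if val is None:
                continue
            j = index.get((feat, val))
            if j is None:
                if (feat, val) not in warned:
                    logger.warning("unseen category %s=%s encoded as zeros", feat, val)
                    warned.add((feat, val))
                continue
            X[i, j] = 1.0
    return X[0] if single else X


def target_vector(records: Sequence[ProcessedRecord]) -> np.ndarray:
    return np.array([r.los_class for r in records], dtype=object)
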