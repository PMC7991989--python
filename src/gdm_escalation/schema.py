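"""Table schemas, the meal-tag taxonomy, and input validation.

Three flat tables flow through the pipeline:

``patients``
    One row per woman: identifier, booking demographics (age in years,
    BMI in kg/m^2), an ethnicity-risk flag, nine binary antenatal risk
    factors, a diabetes-type flag (``GDM`` or one of the excluded types
    ``T1``/``T2``/``MODY``) and the delivery date.

``readings``
    One row per self-monitored blood-glucose value: patient identifier,
    timestamp, prandial meal tag, value in mmol/L and entry method.

``medications``
    One row per self-reported medication event: patient identifier, date
    and a binary medication indicator (only the binary representation is
    used anywhere downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed prandial tag taxonomy: pre/post x {breakfast, lunch, evening meal}.
MEAL_TAGS: tuple[str, ...] = (
    "prebreakfast",
    "postbreakfast",
    "prelunch",
    "postlunch",
    "pre-evening-meal",
    "post-evening-meal",
)

PRE_TAGS: tuple[str, ...] = ("prebreakfast", "prelunch", "pre-evening-meal")
POST_TAGS: tuple[str, ...] = ("postbreakfast", "postlunch", "post-evening-meal")

#: Meal families pool the pre and post tag of one meal; ``all`` is every tag.
TAG_FAMILIES: dict[str, tuple[str, ...]] = {
    "breakfast": ("prebreakfast", "postbreakfast"),
    "lunch": ("prelunch", "postlunch"),
    "evening_meal": ("pre-evening-meal", "post-evening-meal"),
    "all": MEAL_TAGS,
}

#: Binary risk factors recorded at booking.
RISK_FLAGS: tuple[str, ...] = (
    "previous_gdm",
    "family_history",
    "previous_lga_baby",
    "polyhydramnios",
    "glycosuria",
    "macrosomia",
    "missed_ogtt",
    "unable_ogtt",
    "polycystic_ovaries",
)

#: Per-tag alert thresholds (mmol/L). The clinical rule and the raised-run
#: features flag a reading that is strictly above its tag's threshold.
#: Defaults follow NICE-style pregnancy targets: fasting/pre-meal 5.3,
#: one-hour post-meal 7.8. They are configuration, not learned values.
DEFAULT_ALERT_THRESHOLDS: dict[str, float] = {
    "prebreakfast": 5.3,
    "prelunch": 5.3,
    "pre-evening-meal": 5.3,
    "postbreakfast": 7.8,
    "postlunch": 7.8,
    "post-evening-meal": 7.8,
}

DIABETES_TYPES: tuple[str, ...] = ("GDM", "T1", "T2", "MODY")
EXCLUDED_DIABETES_TYPES: tuple[str, ...] = ("T1", "T2", "MODY")

PATIENT_COLUMNS: tuple[str, ...] = (
    ("patient_id", "age", "bmi", "ethnicity_risk")
    + RISK_FLAGS
    + ("diabetes_type", "delivery_date")
)
READING_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "timestamp",
    "meal_tag",
    "bg_mmol",
    "entry_method",
)
MEDICATION_COLUMNS: tuple[str, ...] = ("patient_id", "date", "medication")


class InputError(ValueError):
    """Raised when an input table violates the schema."""


@dataclass
class InputReport:
    """Outcome of :func:`validate_inputs`: a list of human-readable issues."""

    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> None:
        if self.errors:
            raise InputError("; ".join(self.errors))


def _check_columns(df: pd.DataFrame, required: tuple[str, ...], name: str,
                   errors: list[str]) -> bool:
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"{name}: missing column(s) {missing}")
        return False
    return True


def parse_dates(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Return a copy with the named columns coerced to datet64."""
    out = df.copy()
    for col in columns:
        if col in out.columns and not pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = pd.to_datetime(out[col], format="mixed")
    return out


def validate_inputs(patients: pd.DataFrame, readings: pd.DataFrame,
                    medications: pd.DataFrame) -> InputReport:
    """Check schema, tag vocabulary, positivity and date ordering.

    Returns an :class:`InputReport`; callers decide whether to raise.
    """
    errors: list[str] = []
    if _check_columns(patients, PATIENT_COLUMNS, "patients", errors):
        bad_type = ~patients["diabetes_type"].isin(DIABETES_TYPES)
        if bad_type.any():
            rows = patients.index[bad_type].tolist()[:5]
            errors.append(f"patients: unknown diabetes_type at rows {rows}")
        dup = patients["patient_id"].duplicated()
        if dup.any():
            errors.append(
                f"patients: duplicated patient_id "
                f"{sorted(patients.loc[dup, 'patient_id'].unique())[:5]}"
            )
    if _check_columns(readings, READING_COLUMNS, "readings", errors):
        bad_tag = ~readings["meal_tag"].isin(MEAL_TAGS)
        if bad_tag.any():
            tags = sorted(readings.loc[bad_tag, "meal_tag"].unique())[:5]
            errors.append(f"readings: unknown meal_tag value(s) {tags}")
        bg = pd.to_numeric(readings["bg_mmol"], errors="coerce")
        nonpos = bg.le(0) | bg.isna()
        if nonpos.any():
            rows = readings.index[nonpos].tolist()[:5]
            errors.append(f"readings: non-positive or non-numeric bg_mmol at rows {rows}")
        if len(readings):
            known = set(patients.get("patient_id", pd.Series(dtype=object)))
            orphan = ~readings["patient_id"].isin(known)
            if orphan.any():
                ids = sorted(readings.loc[orphan, "patient_id"].unique())[:5]
                errors.append(f"readings: unknown patient_id {ids}")
    if _check_columns(medications, MEDICATION_COLUMNS, "medications", errors):
        if len(medications):
            med = pd.to_numeric(medications["medication"], errors="coerce")
            if not med.isin([0, 1]).all():
                errors.append("medications: medication indicator must be 0/1")
            known = set(patients.get("patient_id", pd.Series(dtype=object)))
            orphan = ~medications["patient_id"].isin(known)
            if orphan.any():
                ids = sorted(medications.loc[orphan, "patient_id"].unique())[:5]
                errors.append(f"medications: unknown patient_id {ids}")
    # Date ordering: no reading after its patient's delivery date.
    if not errors and len(readings):
        pat = parse_dates(patients, ["delivery_date"])
        rd = parse_dates(readings, ["timestamp"])
        merged = rd.merge(pat[["patient_id", "delivery_date"]], on="patient_id")
        late = merged["timestamp"].dt.normalize() > merged["delivery_date"]
        if late.any():
            n = int(late.sum())
            errors.append(f"readings: {n} reading(s) dated after delivery")
    return InputReport(errors=errors)
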