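"""Cohort construction: eligibility, group assignment, descriptive summaries.

A woman enters the analysis only if her demographics are complete, she has
gestational (not pre-existing) diabetes, and she recorded at least 36
glucose readings in her first week of system use. Eligible women are then
assigned to:

* ``diet_diet`` — never any medication event: lifestyle management only;
* ``diet_drug`` — first medication at least ``min_diet_days`` (default 14)
  calendar days after the first reading;
* ``excluded`` (``early_medication``) — medication started before the
  cutoff, i.e. pharmacological treatment began too early to observe a
  meaningful diet-managed period.

"First day of use" is the date of the earliest reading — readings are the
only usage signal in the data model. Day arithmetic is calendar-day,
half-open and 0-based: first medication on day index 14 (the 15th day)
satisfies "at least 14 days".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .schema import (
    EXCLUDED_DIABETES_TYPES,
    InputError,
    TAG_FAMILIES,
)

logger = logging.getLogger(__name__)

GROUPS = ("diet_diet", "diet_drug", "excluded")
EXCLUSION_REASONS = (
    "none",
    "early_medication",
    "sparse_readings",
    "missing_demographics",
    "other_diabetes_type",
)

#: Minimum number of readings in the first week of use.
MIN_FIRST_WEEK_READINGS = 36

LABEL_COLUMNS = (
    "patient_id", "group", "exclusion_reason",
    "first_reading_date", "first_medication_date", "delivery_date",
)


def first_reading_dates(readings: pd.DataFrame) -> pd.Series:
    """Earliest reading timestamp per patient, normalized to midnight."""
    if readings.empty:
        return pd.Series(dtype="datetime64[ns]", name="first_reading_date",
                         index=pd.Index([], name="patient_id"))
    return (
        readings.groupby("patient_id")["timestamp"].min().dt.normalize()
        .rename("first_reading_date")
    )


def apply_eligibility(patients: pd.DataFrame,
                      readings: pd.DataFrame) -> pd.DataFrame:
    """Per-patient eligibility verdicts.

    A patient is ineligible iff (in precedence order) their diabetes-type
    flag is T1/T2/MODY, their age or BMI is missing, or they recorded
    strictly fewer than 36 readings in the half-open week
    ``[first_reading_date, first_reading_date + 7 days)``. A patient with
    no readings at all counts as sparse. The verdict carries the first
    matching reason.

    Returns a frame with ``patient_id``, ``eligible``, ``exclusion_reason``
    and ``first_reading_date``.
    """
    for col in ("patient_id", "age", "bmi", "diabetes_type"):
        if col not in patients.columns:
            raise InputError(f"patients: missing column '{col}'")
    for col in ("patient_id", "timestamp"):
        if col not in readings.columns:
            raise InputError(f"readings: missing column '{col}'")

    first = first_reading_dates(readings)
    out = patients[["patient_id"]].copy()
    out = out.merge(first, on="patient_id", how="left")

    if readings.empty:
        week1 = pd.Series(0, index=out["patient_id"])
    else:
        rd = readings.merge(first, on="patient_id")
        in_week1 = rd["timestamp"] < rd["first_reading_date"] + pd.Timedelta(days=7)
        week1 = rd.loc[in_week1].groupby("patient_id").size()
    week1_counts = out["patient_id"].map(week1).fillna(0).astype(int)

    reason = np.full(len(out), "none", dtype=object)
    sparse = (week1_counts < MIN_FIRST_WEEK_READINGS).to_numpy()
    reason[sparse] = "sparse_readings"
    demo_missing = (
        patients["age"].isna() | patients["bmi"].isna()
    ).to_numpy()
    reason[demo_missing] = "missing_demographics"
    other_type = patients["diabetes_type"].isin(EXCLUDED_DIABETES_TYPES).to_numpy()
    reason[other_type] = "other_diabetes_type"

    out["eligible"] = reason == "none"
    out["exclusion_reason"] = reason
    return out


def assign_groups(eligibility: pd.DataFrame, medications: pd.DataFrame,
                  min_diet_days: int = 14) -> pd.DataFrame:
    """Assign each eligible patient to diet_diet / diet_drug / excluded.

    ``eligibility`` is the output of :func:`apply_eligibility`; patients
    already ineligible keep their verdict. Raises :class:`InputError` on a
    medication event for an unknown patient.
    """
    known = set(eligibility["patient_id"])
    if len(medications):
        orphan = ~medications["patient_id"].isin(known)
        if orphan.any():
            ids = sorted(medications.loc[orphan, "patient_id"].unique())[:5]
            raise InputError(f"medications reference unknown patient_id {ids}")
        first_med = (
            medications.groupby("patient_id")["date"].min().dt.normalize()
            .rename("first_medication_date")
        )
    else:
        first_med = pd.Series(dtype="datetime64[ns]",
                              name="first_medication_date",
                              index=pd.Index([], name="patient_id"))

    out = eligibility.copy()
    out = out.merge(first_med, on="patient_id", how="left")
    if "first_medication_date" not in out.columns:
        out["first_medication_date"] = pd.NaT

    has_med = out["first_medication_date"].notna()
    offset = (out["first_medication_date"] - out["first_reading_date"]).dt.days

    group = np.full(len(out), "excluded", dtype=object)
    reason = out["exclusion_reason"].to_numpy(dtype=object).copy()
    eligible = out["eligible"].to_numpy()

    diet = eligible & ~has_med.to_numpy()
    drug = eligible & has_med.to_numpy() & (offset >= min_diet_days).to_numpy()
    early = eligible & has_med.to_numpy() & (offset < min_diet_days).to_numpy()
    group[diet] = "diet_diet"
    group[drug] = "diet_drug"
    reason[early] = "early_medication"

    out["group"] = group
    out["exclusion_reason"] = reason
    # diet_diet patients by definition have no medication date
    out.loc[out["group"] == "diet_diet", "first_medication_date"] = pd.NaT
    return out.drop(columns=["eligible"])


def build_cohort(patients: pd.DataFrame, readings: pd.DataFrame,
                 medications: pd.DataFrame,
                 min_diet_days: int = 14) -> pd.DataFrame:
    """Eligibility + group assignment in one call; returns the label table."""
    elig = apply_eligibility(patients, readings)
    labels = assign_groups(elig, medications, min_diet_days=min_diet_days)
    labels = labels.merge(
        patients[["patient_id", "delivery_date"]], on="patient_id", how="left"
    )
    return labels[list(LABEL_COLUMNS)]


def cohort_summary(labels: pd.DataFrame, readings: pd.DataFrame) -> dict:
    """Counts per group and exclusion reason plus reading totals.

    Prevalence of diet_drug is reported as a percentage of the analyzed
    cohort (diet_diet + diet_drug), truncated to two decimals (the quoting
    convention for such cohort percentages: 700/1789 reads 39.12%); when
    the analyzed cohort is empty it is ``None`` and flagged undefined.
    Reading counts cover the analyzed patients only and are broken down by
    meal family (breakfast = pre+post breakfast, etc.), so the family
    counts sum to the total.
    """
    group_counts = {g: int((labels["group"] == g).sum()) for g in GROUPS}
    reason_counts = {
        r: int((labels["exclusion_reason"] == r).sum())
        for r in EXCLUSION_REASONS if r != "none"
    }
    n_drug = group_counts["diet_drug"]
    n_analyzed = n_drug + group_counts["diet_diet"]
    if n_analyzed:
        prevalence = np.floor(10000.0 * n_drug / n_analyzed) / 100.0
        undefined = False
    else:
        prevalence = None
        undefined = True

    analyzed_ids = set(
        labels.loc[labels["group"].isin(["diet_diet", "diet_drug"]), "patient_id"]
    )
    if len(readings):
        rd = readings[readings["patient_id"].isin(analyzed_ids)]
        family_counts = {
            fam: int(rd["meal_tag"].isin(tags).sum())
            for fam, tags in TAG_FAMILIES.items() if fam != "all"
        }
    else:
        family_counts = {fam: 0 for fam in TAG_FAMILIES if fam != "all"}
    total = sum(family_counts.values())
    return {
        "n_patients": int(len(labels)),
        "group_counts": group_counts,
        "exclusion_counts": reason_counts,
        "n_analyzed": n_analyzed,
        "prevalence_drug_pct": prevalence,
        "prevalence_undefined": undefined,
        "total_readings": total,
        "tag_family_counts": family_counts,
    }


def delivery_aligned_profile(readings: pd.DataFrame, labels: pd.DataFrame,
                             patients: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean glucose by days-to-delivery.

    Aligns every analyzed patient's readings to her delivery date and
    returns, per group and integer days-to-delivery, the tag-agnostic mean
    glucose, its standard error (NaN when n = 1) and the number of
    readings. Rows with no readings are omitted. Readings dated after
    delivery are excluded from the profile with a logged warning.
    """
    analyzed = labels[labels["group"].isin(["diet_diet", "diet_drug"])]
    rd = readings.merge(
        analyzed[["patient_id", "group"]], on="patient_id", how="inner"
    ).merge(patients[["patient_id", "delivery_date"]], on="patient_id")
    if rd.empty:
        return pd.DataFrame(
            columns=["group", "days_to_delivery", "mean_bg", "se_bg", "n"]
        )
    rd["days_to_delivery"] = (
        rd["delivery_date"] - rd["timestamp"].dt.normalize()
    ).dt.days
    late = rd["days_to_delivery"] < 0
    if late.any():
        logger.warning(
            "%d reading(s) dated after delivery excluded from profile",
            int(late.sum()),
        )
        rd = rd[~late]
    grouped = rd.groupby(["group", "days_to_delivery"])["bg_mmol"]
    prof = grouped.agg(mean_bg="mean", sd="std", n="size").reset_index()
    prof["se_bg"] = prof["sd"] / np.sqrt(prof["n"])
    prof = prof.drop(columns=["sd"]).sort_values(
        ["group", "days_to_delivery"], ascending=[True, False]
    ).reset_index(drop=True)
    return prof[["group", "days_to_delivery", "mean_bg", "se_bg", "n"]]
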