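"""Synthetic GDM monitoring cohorts.

Generates the three pipeline tables (patients, readings, medications) with
the statistical structure the analysis assumes: meal-tagged glucose series
whose diet-drug group runs persistently higher than the diet-diet group,
medication initiation after at least two medication-free weeks, monitoring
periods ending at delivery, Bernoulli missingness, and booking
demographics/risk factors.

Glucose values are drawn from a normal distribution truncated at
0.1 mmol/L (positivity is physiologic; no particular parametric family is
assumed by the downstream analysis) and rounded to 0.1 mmol/L, the
resolution of a home glucometer. Each woman carries a persistent baseline
offset so that weeks from the same woman are correlated — without it,
window-level averages would separate the groups almost perfectly at any
nonzero shift, which is not how real cohorts behave.

The diet-drug shift is applied from day one as a constant offset; the
post-treatment decline of glucose under medication is deliberately not
modelled, because every analysis window ends before the first medication
event.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .schema import (
    MEAL_TAGS,
    MEDICATION_COLUMNS,
    PATIENT_COLUMNS,
    READING_COLUMNS,
    RISK_FLAGS,
)

EPOCH = pd.Timestamp("2019-01-01")

#: Nominal clock hour of each tag's reading.
_TAG_HOURS = {
    "prebreakfast": 7.0,
    "postbreakfast": 9.0,
    "prelunch": 12.5,
    "postlunch": 14.5,
    "pre-evening-meal": 18.0,
    "post-evening-meal": 20.0,
}

EXCLUSION_KINDS = (
    "early_medication",
    "sparse_readings",
    "missing_demographics",
    "other_diabetes_type",
)


def _empty_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    return (
        pd.DataFrame(columns=list(PATIENT_COLUMNS)),
        pd.DataFrame(columns=list(READING_COLUMNS)),
        pd.DataFrame(columns=list(MEDICATION_COLUMNS)),
    )


def _generate(config: SimConfig, rng: np.random.Generator,
              patient_ids: list[str], is_drug: np.ndarray,
              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Core generator for a fixed group assignment."""
    n = len(patient_ids)
    if n == 0:
        return _empty_tables()
    days = config.monitoring_days
    tags = list(MEAL_TAGS[: config.readings_per_day])
    k = len(tags)

    enroll = rng.integers(0, 120, size=n)
    first_date = EPOCH + pd.to_timedelta(enroll, unit="D")
    delivery = first_date + pd.to_timedelta(days, unit="D")

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 16, 52).round(1)
    bmi = np.clip(
        rng.normal(config.bmi_mean, config.bmi_sd, n)
        + config.bmi_delta_drug * is_drug,
        15, 60,
    ).round(1)
    eth_p = np.where(is_drug, config.ethnicity_risk_prob_drug,
                     config.ethnicity_risk_prob)
    ethnicity_risk = (rng.random(n) < eth_p).astype(int)
    flag_p = np.where(is_drug, config.risk_flag_prob_drug, config.risk_flag_prob)
    flags = {f: (rng.random(n) < flag_p).astype(int) for f in RISK_FLAGS}
    baseline = rng.normal(0.0, config.bg_patient_sd, n)
    lo, hi = config.med_range()
    med_start = rng.integers(lo, hi + 1, size=n)

    patients = pd.DataFrame({
        "patient_id": patient_ids,
        "age": age,
        "bmi": bmi,
        "ethnicity_risk": ethnicity_risk,
        **flags,
        "diabetes_type": "GDM",
        "delivery_date": delivery,
    })[list(PATIENT_COLUMNS)]

    # Readings: one scheduled reading per tag per day, Bernoulli dropouts.
    shape = (n, days, k)
    tag_means = np.array([
        config.bg_mean_pre if t.startswith("pre") else config.bg_mean_post
        for t in tags
    ])
    values = (
        tag_means[None, None, :]
        + (config.bg_delta_drug * is_drug)[:, None, None]
        + baseline[:, None, None]
        + rng.normal(0.0, config.bg_sd, shape)
    )
    values = np.maximum(values, 0.1).round(1)
    jitter_min = rng.integers(-30, 31, size=shape)
    keep = rng.random(shape) >= config.missing_rate
    manual = rng.random(shape) < 0.3

    pat_idx, day_idx, tag_idx = np.nonzero(keep)
    hours = np.array([_TAG_HOURS[t] for t in tags])
    minutes = (day_idx * 1440
               + (hours[tag_idx] * 60).astype(int)
               + jitter_min[keep])
    readings = pd.DataFrame({
        "patient_id": np.array(patient_ids, dtype=object)[pat_idx],
        "timestamp": first_date.values[pat_idx]
        + pd.to_timedelta(minutes, unit="m"),
        "meal_tag": np.array(tags, dtype=object)[tag_idx],
        "bg_mmol": values[keep],
        "entry_method": np.where(manual[keep], "manual", "bluetooth"),
    })
    readings = readings.sort_values(
        ["patient_id", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)[list(READING_COLUMNS)]

    # Medication events: daily binary rows from initiation to delivery.
    med_rows = []
    for i in np.nonzero(is_drug)[0]:
        med_days = np.arange(med_start[i], days)
        med_rows.append(pd.DataFrame({
            "patient_id": patient_ids[i],
            "date": first_date[i] + pd.to_timedelta(med_days, unit="D"),
            "medication": 1,
        }))
    if med_rows:
        medications = pd.concat(med_rows, ignore_index=True)
        medications = medications.sort_values(
            ["patient_id", "date"], kind="mergesort"
        ).reset_index(drop=True)[list(MEDICATION_COLUMNS)]
    else:
        medications = _empty_tables()[2]
    return patients, readings, medications


def generate_cohort(config: SimConfig,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Exactly ``round(n_patients * prevalence_drug)`` patients carry
    medication events, with the first event drawn from
    ``med_start_day_range`` (so the 14-day diet rule is always satisfied).
    Two calls with an equal config produce byte-identical tables.
    """
    config.validate()
    if config.n_patients == 0:
        return _empty_tables()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_drug = round(n * config.prevalence_drug)
    is_drug = np.zeros(n, dtype=bool)
    is_drug[rng.permutation(n)[:n_drug]] = True
    ids = [f"P{i:05d}" for i in range(n)]
    return _generate(config, rng, ids, is_drug)


def generate_null_cohort(config: SimConfig,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort in which no feature carries group signal.

    The glucose shift and every demographic difference between groups are
    forced to zero; group labels remain, so downstream discrimination
    metrics calibrate to chance (AUC 0.5 in expectation).
    """
    null_cfg = config.replace(
        bg_delta_drug=0.0,
        bmi_delta_drug=0.0,
        ethnicity_risk_prob_drug=config.ethnicity_risk_prob,
        risk_flag_prob_drug=config.risk_flag_prob,
    )
    return generate_cohort(null_cfg)


def generate_excludable_patients(
    config: SimConfig, kinds: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one patient per requested eligibility violation.

    ``early_medication`` starts medication on day 10 (< 14 diet days);
    ``sparse_readings`` keeps only 20 readings in the first week;
    ``missing_demographics`` blanks the BMI; ``other_diabetes_type`` sets
    the type-1 flag. Each patient violates exactly the requested rule.
    """
    config.validate()
    unknown = [kind for kind in kinds if kind not in EXCLUSION_KINDS]
    if unknown:
        raise ConfigError(
            f"unknown exclusion kind(s) {unknown}; valid: {list(EXCLUSION_KINDS)}"
        )
    if not kinds:
        return _empty_tables()
    rng = np.random.default_rng((config.seed, 0xE))
    ids = [f"X{i:03d}-{kind}" for i, kind in enumerate(kinds)]
    is_drug = np.zeros(len(kinds), dtype=bool)
    patients, readings, medications = _generate(config, rng, ids, is_drug)
    patients = patients.set_index("patient_id", drop=False)
    med_parts = [medications]
    keep_masks = []
    for pid, kind in zip(ids, kinds):
        mask = readings["patient_id"] == pid
        if kind == "early_medication":
            first = readings.loc[mask, "timestamp"].min().normalize()
            med_parts.append(pd.DataFrame({
                "patient_id": [pid],
                "date": [first + pd.Timedelta(days=10)],
                "medication": [1],
            }))
        elif kind == "sparse_readings":
            first = readings.loc[mask, "timestamp"].min().normalize()
            in_week1 = mask & (readings["timestamp"] < first + pd.Timedelta(days=7))
            extra = readings.index[in_week1][20:]
            keep_masks.append(extra)
        elif kind == "missing_demographics":
            patients.loc[pid, "bmi"] = np.nan
        elif kind == "other_diabetes_type":
            patients.loc[pid, "diabetes_type"] = "T1"
    if keep_masks:
        drop = np.concatenate([idx.values for idx in keep_masks])
        readings = readings.drop(index=drop).reset_index(drop=True)
    med_parts = [m for m in med_parts if len(m)]
    if med_parts:
        medications = pd.concat(med_parts, ignore_index=True)
        medications = medications.sort_values(
            ["patient_id", "date"], kind="mergesort"
        ).reset_index(drop=True)[list(MEDICATION_COLUMNS)]
    else:
        medications = _empty_tables()[2]
    return patients.reset_index(drop=True), readings, medications


def write_tables(tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
                 outdir) -> dict[str, str]:
    """Write the three tables as CSV; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = ("patients", "readings", "medications")
    paths = {}
    for name, df in zip(names, tables):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


def read_tables(indir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read patients/readings/medications CSVs, parsing date columns."""
    from pathlib import Path

    from .schema import parse_dates

    indir = Path(indir)
    patients = parse_dates(pd.read_csv(indir / "patients.csv"), ["delivery_date"])
    readings = parse_dates(pd.read_csv(indir / "readings.csv"), ["timestamp"])
    medications = parse_dates(pd.read_csv(indir / "medications.csv"), ["date"])
    return patients, readings, medications
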