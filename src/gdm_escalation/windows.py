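"""Observation windows and the per-window predictor set.

Every prediction is made on a 7-day, half-open window ``[start, end)`` of
one woman's readings:

* diet-drug — the single canonical window ends one day before the first
  medication date, leaving a 1-day gap between the observed week and the
  medication event (first medication on day 20 gives the window
  ``[12, 19)`` with day 19 as the gap).
* diet-diet — training uses one week drawn uniformly from the tiled set of
  non-overlapping candidate weeks inside the monitoring period; validation
  uses every week of that tiling. Drawing the training week from the same
  grid keeps training and validation commensurable.

The predictor set computed on a window comprises, for each meal family
(breakfast, lunch, evening meal, and all readings pooled): mean, SD, min,
max and the ordinary-least-squares slope of glucose against fractional
time-in-days; per-subtag means and extrema for the six pre/post tags;
raised-run counts (number of 3-consecutive-day spans in which a tag's
readings exceeded its alert threshold) for prebreakfast and the three
postprandial tags; and the booking demographics and risk flags. Families
with fewer than two readings yield missing SD/slope, later mean-imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heuristic import heuristic_classify
from .schema import DEFAULT_ALERT_THRESHOLDS, MEAL_TAGS, RISK_FLAGS, TAG_FAMILIES

logger = logging.getLogger(__name__)

WINDOW_DAYS = 7
GAP_DAYS = 1

#: Tags carrying a raised-run count: fasting plus the three postprandial.
RAISED_TAGS = ("prebreakfast", "postbreakfast", "postlunch", "post-evening-meal")

#: Non-feature columns of the window table.
META_COLUMNS = ("patient_id", "window_index", "start", "end", "label",
                "heuristic_positive")


def _safe(tag: str) -> str:
    return tag.replace("-", "_")


@dataclass(frozen=True)
class ObservationWindow:
    """A labeled 7-day half-open span of one patient's readings."""

    patient_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    label: str  # diet_diet or diet_drug
    window_index: int = 0

    def __post_init__(self):
        if self.end - self.start != pd.Timedelta(days=WINDOW_DAYS):
            raise ValueError("window must span exactly 7 days")


def _drug_window(row) -> ObservationWindow | None:
    """Canonical week-before-medication window, or None if infeasible."""
    med = row["first_medication_date"]
    start = med - pd.Timedelta(days=WINDOW_DAYS + GAP_DAYS)
    if start < row["first_reading_date"]:
        logger.warning(
            "patient %s: medication too close to first reading for a "
            "gap-adjusted window; skipped", row["patient_id"],
        )
        return None
    return ObservationWindow(row["patient_id"], start,
                             start + pd.Timedelta(days=WINDOW_DAYS),
                             "diet_drug")


def _diet_candidates(row) -> list[ObservationWindow]:
    """Non-overlapping weeks tiled from the first reading date forward."""
    first = row["first_reading_date"]
    delivery = row["delivery_date"]
    n_weeks = (delivery - first).days // WINDOW_DAYS
    out = []
    for k in range(n_weeks):
        start = first + pd.Timedelta(days=WINDOW_DAYS * k)
        out.append(ObservationWindow(row["patient_id"], start,
                                     start + pd.Timedelta(days=WINDOW_DAYS),
                                     "diet_diet", window_index=k))
    return out


def training_window(row, rng: np.random.Generator) -> ObservationWindow | None:
    """One training window for a labeled patient.

    ``row`` is a label-table row (mapping-like). Diet-drug patients get the
    canonical week before medication; diet-diet patients get one week drawn
    uniformly from the tiled candidate set using ``rng``.
    """
    if row["group"] == "diet_drug":
        return _drug_window(row)
    candidates = _diet_candidates(row)
    if not candidates:
        return None
    return candidates[int(rng.integers(len(candidates)))]


def validation_windows(row) -> list[ObservationWindow]:
    """All validation windows for a labeled patient.

    Diet-drug: the single week-before-medication window. Diet-diet: every
    non-overlapping week tiled over the monitoring period (a partial
    trailing week is dropped).
    """
    if row["group"] == "diet_drug":
        w = _drug_window(row)
        return [] if w is None else [w]
    return _diet_candidates(row)


def _ols_slope(t: np.ndarray, v: np.ndarray) -> float:
    """OLS slope of glucose on fractional days; NaN if under-determined."""
    if len(v) < 2 or np.ptp(t) == 0:
        return np.nan
    tc = t - t.mean()
    return float(np.dot(tc, v - v.mean()) / np.dot(tc, tc))


def raised_run_count(day_flags, run_length: int = 3,
                     mode: str = "overlapping") -> int:
    """Number of ``run_length``-consecutive-day alert runs in a flag vector.

    ``day_flags`` holds one boolean per calendar day of the window. In
    ``overlapping`` mode a sliding window of length 3 is counted at every
    position where all days are alerted (max 5 in a 7-day week); in
    ``nonoverlapping`` mode runs are consumed greedily left to right.
    """
    flags = np.asarray(day_flags, dtype=bool)
    if mode == "overlapping":
        return int(sum(flags[i:i + run_length].all()
                       for i in range(len(flags) - run_length + 1)))
    if mode == "nonoverlapping":
        count, i = 0, 0
        while i <= len(flags) - run_length:
            if flags[i:i + run_length].all():
                count += 1
                i += run_length
            else:
                i += 1
        return count
    raise ValueError("mode must be 'overlapping' or 'nonoverlapping'")


def raised_3day_count(times_days: np.ndarray, values: np.ndarray,
                      threshold: float, mode: str = "overlapping") -> int:
    """Raised-run count for one tag's readings within a window.

    ``times_days`` are fractional days since window start. A calendar day
    is alerted when any reading of the tag that day is strictly above the
    threshold.
    """
    flags = np.zeros(WINDOW_DAYS, dtype=bool)
    day = np.floor(times_days).astype(int)
    alerted = day[values > threshold]
    flags[alerted[(alerted >= 0) & (alerted < WINDOW_DAYS)]] = True
    return raised_run_count(flags, mode=mode)


def feature_names() -> list[str]:
    """Ordered list of all predictor names in the window feature vector."""
    names = []
    for fam in TAG_FAMILIES:
        names += [f"{fam}_{s}" for s in ("mean", "sd", "min", "max", "slope")]
    for tag in MEAL_TAGS:
        names += [f"{_safe(tag)}_{s}" for s in ("mean", "min", "max")]
    names += [f"raised3_{_safe(tag)}" for tag in RAISED_TAGS]
    names += ["age", "bmi", "ethnicity_risk", *RISK_FLAGS]
    return names


def extract_features(window: ObservationWindow, readings: pd.DataFrame,
                     demographics, alert_thresholds=None,
                     raised_mode: str = "overlapping") -> dict[str, float]:
    """Compute the full predictor vector for one window.

    ``readings`` may contain any rows; only those of the window's patient
    with timestamp in ``[start, end)`` contribute. ``demographics`` is the
    patient's row (mapping-like) providing age, BMI and risk flags.
    """
    if alert_thresholds is None:
        alert_thresholds = DEFAULT_ALERT_THRESHOLDS
    rd = readings
    if "patient_id" in rd.columns:
        rd = rd[rd["patient_id"] == window.patient_id]
    mask = (rd["timestamp"] >= window.start) & (rd["timestamp"] < window.end)
    rd = rd.loc[mask]
    t = ((rd["timestamp"] - window.start) / pd.Timedelta(days=1)).to_numpy(float)
    v = rd["bg_mmol"].to_numpy(float)
    tags = rd["meal_tag"].to_numpy(object)

    out: dict[str, float] = {}
    for fam, fam_tags in TAG_FAMILIES.items():
        sel = np.isin(tags, fam_tags)
        fv, ft = v[sel], t[sel]
        if len(fv):
            out[f"{fam}_mean"] = float(fv.mean())
            out[f"{fam}_min"] = float(fv.min())
            out[f"{fam}_max"] = float(fv.max())
            out[f"{fam}_sd"] = float(fv.std(ddof=1)) if len(fv) >= 2 else np.nan
            out[f"{fam}_slope"] = _ols_slope(ft, fv)
        else:
            for s in ("mean", "sd", "min", "max", "slope"):
                out[f"{fam}_{s}"] = np.nan
    for tag in MEAL_TAGS:
        sel = tags == tag
        sv = v[sel]
        p = _safe(tag)
        out[f"{p}_mean"] = float(sv.mean()) if len(sv) else np.nan
        out[f"{p}_min"] = float(sv.min()) if len(sv) else np.nan
        out[f"{p}_max"] = float(sv.max()) if len(sv) else np.nan
    for tag in RAISED_TAGS:
        sel = tags == tag
        out[f"raised3_{_safe(tag)}"] = raised_3day_count(
            t[sel], v[sel], alert_thresholds[tag], mode=raised_mode
        )
    out["age"] = float(demographics["age"])
    out["bmi"] = float(demographics["bmi"])
    out["ethnicity_risk"] = float(demographics["ethnicity_risk"])
    for flag in RISK_FLAGS:
        out[flag] = float(demographics[flag])
    return out


def build_window_table(labels: pd.DataFrame, readings: pd.DataFrame,
                       patients: pd.DataFrame, alert_thresholds=None,
                       raised_mode: str = "overlapping") -> pd.DataFrame:
    """Feature matrix over every validation window of the analyzed cohort.

    One row per window: metadata (patient, window index, span, label), the
    full predictor vector, and the clinical-heuristic decision for the
    window's readings (used for the heuristic operating point). Diet-drug
    patients contribute their single canonical window, diet-diet patients
    every tiled week; a diet-drug patient whose gap-adjusted window is
    infeasible is skipped with a warning.
    """
    if alert_thresholds is None:
        alert_thresholds = DEFAULT_ALERT_THRESHOLDS
    analyzed = labels[labels["group"].isin(["diet_diet", "diet_drug"])]
    demo = patients.set_index("patient_id")
    by_patient = dict(tuple(readings.groupby("patient_id")))
    rows = []
    for _, lab in analyzed.iterrows():
        pid = lab["patient_id"]
        rd = by_patient.get(pid)
        if rd is None:
            continue
        for w in validation_windows(lab):
            feats = extract_features(w, rd, demo.loc[pid],
                                     alert_thresholds, raised_mode)
            span = rd[(rd["timestamp"] >= w.start) & (rd["timestamp"] < w.end)]
            decision = heuristic_classify(span, alert_thresholds)
            rows.append({
                "patient_id": pid,
                "window_index": w.window_index,
                "start": w.start,
                "end": w.end,
                "label": w.label,
                "heuristic_positive": int(decision.positive),
                **feats,
            })
    cols = list(META_COLUMNS) + feature_names()
    return pd.DataFrame(rows, columns=cols)
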