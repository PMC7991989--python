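"""Eligibility rules, group assignment and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from gdm_escalation.cohort import (
    apply_eligibility,
    assign_groups,
    build_cohort,
    cohort_summary,
    delivery_aligned_profile,
)
from gdm_escalation.schema import InputError
from tests.conftest import empty_medications, make_patient, make_readings


def meds(pid, date):
    return pd.DataFrame({
        "patient_id": [pid], "date": [pd.Timestamp(date)], "medication": [1]
    })


class TestEligibility:
    def test_36_readings_first_week_is_eligible(self):
        # "fewer than 36" excludes only strictly fewer
        readings = make_readings(n_days=6, per_day=6)
        verdict = apply_eligibility(make_patient(), readings)
        assert len(readings) == 36
        assert verdict["eligible"].iloc[0]

    def test_35_readings_first_week_is_sparse(self):
        readings = make_readings(n_days=6, per_day=6).iloc[:-1]
        verdict = apply_eligibility(make_patient(), readings)
        assert not verdict["eligible"].iloc[0]
        assert verdict["exclusion_reason"].iloc[0] == "sparse_readings"

    def test_week_boundary_is_half_open(self):
        # 35 readings inside [day0, day7) plus one exactly at day 7 must
        # not rescue the patient
        readings = make_readings(n_days=6, per_day=6).iloc[:-1]
        extra = make_readings(n_days=1, per_day=1)
        extra["timestamp"] = pd.Timestamp("2019-01-08 07:00")
        verdict = apply_eligibility(make_patient(),
                                    pd.concat([readings, extra]))
        assert verdict["exclusion_reason"].iloc[0] == "sparse_readings"

    def test_missing_bmi_excluded(self):
        verdict = apply_eligibility(make_patient(bmi=np.nan),
                                    make_readings(n_days=7))
        assert verdict["exclusion_reason"].iloc[0] == "missing_demographics"

    def test_other_diabetes_type_takes_precedence(self):
        verdict = apply_eligibility(
            make_patient(bmi=np.nan, diabetes_type="MODY"),
            make_readings(n_days=2),
        )
        assert verdict["exclusion_reason"].iloc[0] == "other_diabetes_type"

    def test_patient_without_readings_is_sparse(self):
        verdict = apply_eligibility(make_patient(), make_readings().iloc[0:0])
        assert verdict["exclusion_reason"].iloc[0] == "sparse_readings"


class TestGroupAssignment:
    def test_medication_on_day_14_is_diet_drug(self):
        # day index 14 is the 15th day: "at least 14 days" is satisfied
        labels = build_cohort(make_patient(), make_readings(n_days=7),
                              meds("P1", "2019-01-15"))
        assert labels["group"].iloc[0] == "diet_drug"

    def test_medication_on_day_13_is_excluded(self):
        labels = build_cohort(make_patient(), make_readings(n_days=7),
                              meds("P1", "2019-01-14"))
        assert labels["group"].iloc[0] == "excluded"
        assert labels["exclusion_reason"].iloc[0] == "early_medication"

    def test_medication_on_day_10_is_early(self):
        labels = build_cohort(make_patient(), make_readings(n_days=7),
                              meds("P1", "2019-01-11"))
        assert labels["exclusion_reason"].iloc[0] == "early_medication"

    def test_no_medication_is_diet_diet(self):
        labels = build_cohort(make_patient(), make_readings(n_days=7),
                              empty_medications())
        assert labels["group"].iloc[0] == "diet_diet"
        assert labels["first_medication_date"].isna().all()

    def test_unknown_patient_medication_rejected(self):
        elig = apply_eligibility(make_patient(), make_readings(n_days=7))
        with pytest.raises(InputError, match="unknown patient_id"):
            assign_groups(elig, meds("GHOST", "2019-02-01"))

    def test_min_diet_days_configurable(self):
        labels = build_cohort(make_patient(), make_readings(n_days=7),
                              meds("P1", "2019-01-11"), min_diet_days=10)
        assert labels["group"].iloc[0] == "diet_drug"


class TestCohortInvariants:
    def test_partition_and_order_invariance(self, tiny_cohort, rng):
        patients, readings, medications = tiny_cohort
        labels = build_cohort(patients, readings, medications)
        assert len(labels) == len(patients)
        assert labels["group"].isin(["diet_diet", "diet_drug", "excluded"]).all()
        # excluded <=> a reason is recorded
        excl = labels["group"] == "excluded"
        assert (labels.loc[excl, "exclusion_reason"] != "none").all()
        assert (labels.loc[~excl, "exclusion_reason"] == "none").all()

        shuffled = build_cohort(
            patients.sample(frac=1, random_state=3),
            readings.sample(frac=1, random_state=4),
            medications.sample(frac=1, random_state=5),
        )
        merged = labels.merge(shuffled, on="patient_id", suffixes=("", "_s"))
        assert (merged["group"] == merged["group_s"]).all()

    def test_diet_drug_respects_14_day_rule(self, tiny_cohort):
        labels = build_cohort(*tiny_cohort)
        drug = labels[labels["group"] == "diet_drug"]
        gap = (drug["first_medication_date"] - drug["first_reading_date"]).dt.days
        assert (gap >= 14).all()


class TestCohortSummary:
    def test_prevalence_arithmetic(self):
        labels = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(1789)],
            "group": ["diet_drug"] * 700 + ["diet_diet"] * 1089,
            "exclusion_reason": "none",
        })
        s = cohort_summary(labels, make_readings().iloc[0:0])
        assert s["prevalence_drug_pct"] == 39.12
        assert s["n_analyzed"] == 1789

    def test_family_counts_sum_to_total(self, tiny_cohort):
        patients, readings, medications = tiny_cohort
        labels = build_cohort(patients, readings, medications)
        s = cohort_summary(labels, readings)
        assert sum(s["tag_family_counts"].values()) == s["total_readings"]
        assert sum(s["group_counts"].values()) == len(patients)

    def test_empty_cohort_flags_undefined_prevalence(self):
        labels = pd.DataFrame(columns=["patient_id", "group",
                                       "exclusion_reason"])
        s = cohort_summary(labels, make_readings().iloc[0:0])
        assert s["prevalence_drug_pct"] is None
        assert s["prevalence_undefined"]
        assert s["total_readings"] == 0


class TestDeliveryProfile:
    def _labels(self):
        return pd.DataFrame({
            "patient_id": ["P1"], "group": ["diet_diet"],
            "exclusion_reason": ["none"],
        })

    def test_single_reading_day(self):
        patients = make_patient(delivery=pd.Timestamp("2019-01-31"))
        readings = make_readings(n_days=1, per_day=1, value=6.0)
        prof = delivery_aligned_profile(readings, self._labels(), patients)
        assert len(prof) == 1
        row = prof.iloc[0]
        assert row["mean_bg"] == 6.0 and row["n"] == 1
        assert np.isnan(row["se_bg"])

    def test_two_reading_day_hand_arithmetic(self):
        patients = make_patient(delivery=pd.Timestamp("2019-01-31"))
        readings = make_readings(n_days=1, per_day=2)
        readings["bg_mmol"] = [5.0, 7.0]
        prof = delivery_aligned_profile(readings, self._labels(), patients)
        row = prof.iloc[0]
        # SD = sqrt(2), SE = sqrt(2)/sqrt(2) = 1
        assert row["mean_bg"] == 6.0 and row["se_bg"] == pytest.approx(1.0)
        assert row["days_to_delivery"] == 30

    def test_reading_after_delivery_excluded(self, caplog):
        patients = make_patient(delivery=pd.Timestamp("2019-01-03"))
        readings = make_readings(n_days=5, per_day=1)
        with caplog.at_level("WARNING"):
            prof = delivery_aligned_profile(readings, self._labels(), patients)
        assert (prof["days_to_delivery"] >= 0).all()
        assert prof["n"].sum() == 3
        assert "after delivery" in caplog.text

    def test_groups_separate_under_configured_shift(self):
        from gdm_escalation.config import SimConfig
        from gdm_escalation.synthetic import generate_cohort

        patients, readings, medications = generate_cohort(
            SimConfig(n_patients=150, bg_delta_drug=2.0, seed=6)
        )
        labels = build_cohort(patients, readings, medications)
        prof = delivery_aligned_profile(readings, labels, patients)
        wide = prof.pivot_table(index="days_to_delivery", columns="group",
                                values="mean_bg")
        ns = prof.pivot_table(index="days_to_delivery", columns="group",
                              values="n")
        ok = (ns["diet_diet"] >= 20) & (ns["diet_drug"] >= 20)
        above = (wide.loc[ok, "diet_drug"] > wide.loc[ok, "diet_diet"])
        assert above.mean() >= 0.95
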