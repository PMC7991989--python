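"""Window extraction rules and the per-window feature vector."""

import numpy as np
import pandas as pd
import pytest

from gdm_escalation.schema import DEFAULT_ALERT_THRESHOLDS
from gdm_escalation.windows import (
    ObservationWindow,
    build_window_table,
    extract_features,
    raised_3day_count,
    raised_run_count,
    training_window,
    validation_windows,
)
from tests.conftest import make_patient, make_readings
from tests.oracles import naive_features

D0 = pd.Timestamp("2019-01-01")


def label_row(group="diet_diet", first_reading=D0, med_day=None,
              monitoring_days=28):
    return {
        "patient_id": "P1",
        "group": group,
        "first_reading_date": first_reading,
        "first_medication_date": (
            first_reading + pd.Timedelta(days=med_day)
            if med_day is not None else pd.NaT
        ),
        "delivery_date": first_reading + pd.Timedelta(days=monitoring_days),
    }


class TestTrainingWindow:
    def test_medication_day_20_gives_window_12_to_19(self, rng):
        w = training_window(label_row("diet_drug", med_day=20), rng)
        assert w.start == D0 + pd.Timedelta(days=12)
        assert w.end == D0 + pd.Timedelta(days=19)  # day 19 is the gap day

    def test_gap_day_never_inside_window(self, rng):
        for med_day in range(9, 25):
            w = training_window(label_row("diet_drug", med_day=med_day), rng)
            assert w.end <= (D0 + pd.Timedelta(days=med_day - 1))

    def test_infeasible_drug_window_skipped(self, rng, caplog):
        with caplog.at_level("WARNING"):
            w = training_window(label_row("diet_drug", med_day=7), rng)
        assert w is None
        assert "skipped" in caplog.text

    def test_single_candidate_week_always_chosen(self, rng):
        row = label_row(monitoring_days=7)
        for _ in range(5):
            w = training_window(row, rng)
            assert (w.start, w.end) == (D0, D0 + pd.Timedelta(days=7))

    def test_fixed_seed_reproduces_random_week(self):
        row = label_row(monitoring_days=56)
        picks = [training_window(row, np.random.default_rng(9)).start
                 for _ in range(3)]
        assert len(set(picks)) == 1


class TestValidationWindows:
    def test_21_days_tile_into_3_weeks(self):
        ws = validation_windows(label_row(monitoring_days=21))
        assert len(ws) == 3
        starts = [w.start for w in ws]
        assert starts == [D0 + pd.Timedelta(days=7 * k) for k in range(3)]

    def test_partial_trailing_week_dropped(self):
        assert len(validation_windows(label_row(monitoring_days=20))) == 2

    def test_drug_patient_has_exactly_one_window(self):
        ws = validation_windows(label_row("diet_drug", med_day=20))
        assert len(ws) == 1
        assert ws[0].end == D0 + pd.Timedelta(days=19)

    def test_diet_windows_pairwise_nonoverlapping(self):
        ws = validation_windows(label_row(monitoring_days=56))
        for a, b in zip(ws, ws[1:]):
            assert a.end <= b.start

    def test_window_span_enforced(self):
        with pytest.raises(ValueError, match="7 days"):
            ObservationWindow("P1", D0, D0 + pd.Timedelta(days=6), "diet_diet")


class TestRaisedRuns:
    @pytest.mark.parametrize("pattern,expected", [
        ([1, 1, 1, 0, 0, 0, 0], 1),
        ([1, 1, 1, 1, 0, 0, 0], 2),  # windows at days 0-2 and 1-3
        ([0, 0, 0, 0, 0, 0, 0], 0),
        ([1, 1, 1, 1, 1, 1, 1], 5),
        ([1, 1, 0, 1, 1, 0, 1], 0),
    ])
    def test_overlapping_counts(self, pattern, expected):
        assert raised_run_count(pattern) == expected

    def test_nonoverlapping_consumes_runs(self):
        assert raised_run_count([1] * 7, mode="nonoverlapping") == 2
        assert raised_run_count([1, 1, 1, 1, 0, 0, 0],
                                mode="nonoverlapping") == 1

    def test_day_aggregation_any_reading_alerts_the_day(self):
        # two readings on day 0, one above threshold, alert the day
        times = np.array([0.3, 0.7, 1.3, 2.3])
        values = np.array([5.0, 8.0, 8.0, 8.0])
        assert raised_3day_count(times, values, threshold=7.8) == 1


class TestExtractFeatures:
    def _window(self):
        return ObservationWindow("P1", D0, D0 + pd.Timedelta(days=7),
                                 "diet_diet")

    def test_constant_series(self):
        readings = make_readings(n_days=7, per_day=6, value=6.0)
        f = extract_features(self._window(), readings, make_patient().iloc[0])
        assert f["all_mean"] == 6.0
        assert f["all_sd"] == 0.0
        assert f["all_min"] == f["all_max"] == 6.0
        assert f["all_slope"] == pytest.approx(0.0)

    def test_two_point_slope(self):
        readings = make_readings(n_days=2, per_day=1)
        readings["bg_mmol"] = [5.0, 7.0]
        # readings sit exactly 1 day apart -> slope 2 mmol/L/day
        f = extract_features(self._window(), readings, make_patient().iloc[0])
        assert f["all_slope"] == pytest.approx(2.0)

    def test_sparse_family_yields_missing_sd_and_slope(self):
        readings = make_readings(n_days=1, per_day=1)  # prebreakfast only
        f = extract_features(self._window(), readings, make_patient().iloc[0])
        assert np.isnan(f["lunch_mean"])
        assert np.isnan(f["breakfast_sd"])
        assert np.isnan(f["breakfast_slope"])

    def test_min_mean_max_ordering(self, medium_cohort):
        from gdm_escalation.cohort import build_cohort

        patients, readings, medications = medium_cohort
        labels = build_cohort(patients, readings, medications)
        table = build_window_table(labels.head(60), readings, patients)
        for fam in ("breakfast", "lunch", "evening_meal", "all"):
            ok = table[f"{fam}_mean"].notna()
            assert (table.loc[ok, f"{fam}_min"]
                    <= table.loc[ok, f"{fam}_mean"] + 1e-12).all()
            assert (table.loc[ok, f"{fam}_mean"]
                    <= table.loc[ok, f"{fam}_max"] + 1e-12).all()

    def test_matches_naive_oracle_on_random_windows(self, rng):
        from gdm_escalation.config import SimConfig
        from gdm_escalation.synthetic import generate_cohort

        patients, readings, _ = generate_cohort(
            SimConfig(n_patients=12, monitoring_days=28, seed=21,
                      missing_rate=0.3)
        )
        demo = patients.set_index("patient_id")
        for _ in range(60):
            pid = patients["patient_id"].iloc[int(rng.integers(len(patients)))]
            start = D0 + pd.Timedelta(days=int(rng.integers(0, 140)))
            w = ObservationWindow(pid, start, start + pd.Timedelta(days=7),
                                  "diet_diet")
            got = extract_features(w, readings, demo.loc[pid])
            want = naive_features(w, readings, demo.loc[pid],
                                  DEFAULT_ALERT_THRESHOLDS)
            assert set(got) == set(want)
            for k in want:
                if isinstance(want[k], float) and np.isnan(want[k]):
                    assert np.isnan(got[k]), k
                else:
                    assert got[k] == pytest.approx(want[k]), k


class TestWindowTable:
    def test_every_window_inside_monitoring_period(self, tiny_cohort):
        from gdm_escalation.cohort import build_cohort

        patients, readings, medications = tiny_cohort
        labels = build_cohort(patients, readings, medications)
        table = build_window_table(labels, readings, patients)
        merged = table.merge(labels, on="patient_id")
        assert (merged["start"] >= merged["first_reading_date"]).all()
        assert (merged["end"] <= merged["delivery_date"]).all()
        drug = merged["label"] == "diet_drug"
        assert (
            merged.loc[drug, "end"]
            <= merged.loc[drug, "first_medication_date"]
            - pd.Timedelta(days=1)
        ).all()

    def test_drug_patients_contribute_one_window_each(self, tiny_cohort):
        from gdm_escalation.cohort import build_cohort

        patients, readings, medications = tiny_cohort
        labels = build_cohort(patients, readings, medications)
        table = build_window_table(labels, readings, patients)
        per_drug = table[table["label"] == "diet_drug"].groupby("patient_id").size()
        assert (per_drug == 1).all()
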