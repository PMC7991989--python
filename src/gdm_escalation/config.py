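"""Configuration objects for the simulator and the end-to-end run.

Both configs are plain dataclasses that round-trip through YAML, so a run
directory can always be reproduced from its serialized config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .schema import DEFAULT_ALERT_THRESHOLDS, MEAL_TAGS


class ConfigError(ValueError):
    """Raised when a configuration value is out of range; names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic GDM monitoring cohort.

    The generator emulates the data regime of an mHealth glucose diary:
    one reading per meal tag per day over a monitoring period that ends at
    delivery, with Bernoulli dropouts, a persistent per-patient glycaemic
    baseline, and a constant upward shift for women who will go on to need
    pharmacological treatment (the diet-drug group).

    Parameters
    ----------
    n_patients:
        Cohort size.
    prevalence_drug:
        Fraction of patients assigned to the diet-drug group; the default
        matches the ~39% treatment rate typical of monitored GDM cohorts.
    monitoring_days:
        Days from first reading to delivery (>= 21 so that diet-diet
        patients contribute at least three validation weeks).
    readings_per_day:
        Scheduled readings per day, one per tag, in taxonomy order (1-6).
    bg_mean_pre, bg_mean_post:
        Diet-diet population means (mmol/L) for pre- and post-prandial tags.
    bg_delta_drug:
        Additive shift (mmol/L) applied to every reading of a diet-drug
        patient for the whole monitoring period.
    bg_sd:
        Within-patient reading-to-reading noise SD (mmol/L).
    bg_patient_sd:
        SD of the persistent per-patient baseline offset (mmol/L); this is
        what makes windows from the same woman correlated.
    med_start_day_range:
        Closed integer interval of first-medication days for diet-drug
        patients; must lie within [15, monitoring_days - 7], which is also
        the default (``None``).
    missing_rate:
        Probability that a scheduled reading is never entered.
    age_mean, age_sd, bmi_mean, bmi_sd:
        Booking demographics (years, kg/m^2).
    bmi_delta_drug:
        Additive BMI shift for diet-drug patients (demographic signal).
    ethnicity_risk_prob / ethnicity_risk_prob_drug:
        Probability of the ethnicity-risk flag per group.
    risk_flag_prob / risk_flag_prob_drug:
        Per-flag probability of each binary risk factor per group.
    seed:
        Master seed; equal configs produce byte-identical tables.
    """

    n_patients: int = 500
    prevalence_drug: float = 0.3912
    monitoring_days: int = 56
    readings_per_day: int = 6
    bg_mean_pre: float = 4.9
    bg_mean_post: float = 6.2
    bg_delta_drug: float = 0.8
    bg_sd: float = 0.9
    bg_patient_sd: float = 0.6
    med_start_day_range: tuple[int, int] | None = None
    missing_rate: float = 0.10
    age_mean: float = 32.0
    age_sd: float = 5.0
    bmi_mean: float = 29.0
    bmi_sd: float = 5.0
    bmi_delta_drug: float = 2.0
    ethnicity_risk_prob: float = 0.25
    ethnicity_risk_prob_drug: float = 0.40
    risk_flag_prob: float = 0.10
    risk_flag_prob_drug: float = 0.18
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if not 0.0 <= self.prevalence_drug <= 1.0:
            raise ConfigError("prevalence_drug must be in [0, 1]")
        if self.monitoring_days < 21:
            raise ConfigError("monitoring_days must be >= 21")
        if not 1 <= self.readings_per_day <= len(MEAL_TAGS):
            raise ConfigError(
                f"readings_per_day must be in [1, {len(MEAL_TAGS)}]"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        lo, hi = self.med_range()
        if lo > hi:
            raise ConfigError("med_start_day_range must be a valid interval")
        if lo < 15 or hi > self.monitoring_days - 7:
            raise ConfigError(
                "med_start_day_range must lie within "
                f"[15, monitoring_days - 7] = [15, {self.monitoring_days - 7}]"
            )
        for name in ("bg_mean_pre", "bg_mean_post", "bg_sd", "bg_patient_sd",
                     "age_sd", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("ethnicity_risk_prob", "ethnicity_risk_prob_drug",
                     "risk_flag_prob", "risk_flag_prob_drug"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        return self

    def med_range(self) -> tuple[int, int]:
        if self.med_start_day_range is None:
            return (15, self.monitoring_days - 7)
        return self.med_start_day_range

    def replace(self, **changes: Any) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, serialized alongside outputs."""

    sim: SimConfig | None = field(default_factory=SimConfig)
    #: Alternatively, paths to pre-existing patients/readings/medications CSVs.
    input_dir: str | None = None
    output_dir: str = "gdm_run"
    min_diet_days: int = 14
    outlier_percentile: float = 0.95
    fit_on: str = "all_population"  # or "train_only"
    alert_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALERT_THRESHOLDS)
    )
    raised_mode: str = "overlapping"
    alpha: float = 0.75
    cv_folds: int = 5
    selection_rule: str = "min"  # or "1se"
    train_frac: float = 0.7
    n_reps: int = 100
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.sim is not None:
            self.sim.validate()
        elif self.input_dir is None:
            raise ConfigError("either sim or input_dir must be set")
        if self.min_diet_days < 0:
            raise ConfigError("min_diet_days must be >= 0")
        if not 0.0 < self.outlier_percentile <= 1.0:
            raise ConfigError("outlier_percentile must be in (0, 1]")
        if self.fit_on not in ("all_population", "train_only"):
            raise ConfigError("fit_on must be 'all_population' or 'train_only'")
        if self.raised_mode not in ("overlapping", "nonoverlapping"):
            raise ConfigError("raised_mode must be 'overlapping' or 'nonoverlapping'")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha (elastic-net mixing) must be in [0, 1]")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.selection_rule not in ("min", "1se"):
            raise ConfigError("selection_rule must be 'min' or '1se'")
        if not 0.0 < self.train_frac < 1.0:
            raise ConfigError("train_frac must be in (0, 1)")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        missing = [t for t in MEAL_TAGS if t not in self.alert_thresholds]
        if missing:
            raise ConfigError(f"alert_thresholds missing tag(s) {missing}")
        return self

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.sim is not None and self.sim.med_start_day_range is not None:
            d["sim"]["med_start_day_range"] = list(self.sim.med_start_day_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        sim = d.get("sim")
        if sim is not None:
            sim = dict(sim)
            if sim.get("med_start_day_range") is not None:
                sim["med_start_day_range"] = tuple(sim["med_start_day_range"])
            d["sim"] = SimConfig(**sim)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
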