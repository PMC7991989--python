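"""Population-level outlier filtering and mean imputation.

Self-monitored glucose is noisy: inconclusive tests (insufficient sample,
contaminated strip) can produce implausibly high values that would bias
training. The filter learns the empirical 95th percentile of the pooled
glucose values and drops readings strictly above it; a reading exactly at
the cutoff is retained. Only a high-side cutoff is applied — non-positive
values are rejected at schema validation instead.

Missing feature values (e.g. a window with too few readings of one tag to
compute an SD or slope) are replaced by the population mean of that
feature.

Both parameter fits support two policies: ``all_population`` pools every
row (the historical-analysis convention, which leaks a small amount of
validation information into the cutoff and the means) and ``train_only``,
which fits on training-split rows only and is the recommended mode for
honest prospective estimates. Parameters are serializable so any run is
auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Learned preprocessing parameters.

    ``bg_cutoff`` is the glucose exclusion threshold in mmol/L;
    ``imputation_means`` maps each numeric predictor to its fill value;
    ``fitted_on`` records which rows the fit saw.
    """

    bg_cutoff: float | None = None
    imputation_means: dict[str, float] = field(default_factory=dict)
    fitted_on: str = "all_population"

    def to_dict(self) -> dict:
        return {
            "bg_cutoff": self.bg_cutoff,
            "imputation_means": dict(self.imputation_means),
            "fitted_on": self.fitted_on,
        }


def fit_bg_cutoff(readings: pd.DataFrame, percentile: float = 0.95) -> float:
    """Empirical percentile of all supplied glucose values.

    Uses the linear-interpolation percentile definition (interpolates
    between adjacent order statistics). Raises on an empty table.
    """
    if len(readings) == 0:
        raise ValueError("cannot fit a glucose cutoff on an empty table")
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must be in (0, 1]")
    return float(np.quantile(readings["bg_mmol"].to_numpy(float),
                             percentile, method="linear"))


def filter_outliers(readings: pd.DataFrame, bg_cutoff: float) -> pd.DataFrame:
    """Drop readings with glucose strictly above the cutoff."""
    if len(readings) == 0:
        return readings.copy()
    keep = readings["bg_mmol"] <= bg_cutoff
    removed = int((~keep).sum())
    if removed:
        logger.info("outlier filter removed %d of %d readings (cutoff %.2f)",
                    removed, len(readings), bg_cutoff)
    return readings.loc[keep].reset_index(drop=True)


def fit_imputation_means(features: pd.DataFrame,
                         columns: list[str] | None = None) -> dict[str, float]:
    """Arithmetic mean of the non-missing entries of each numeric predictor.

    Raises if a requested predictor has no observed values at all.
    """
    if columns is None:
        columns = [c for c in features.columns
                   if pd.api.types.is_numeric_dtype(features[c])]
    means: dict[str, float] = {}
    for col in columns:
        vals = features[col].to_numpy(float)
        mask = ~np.isnan(vals)
        if not mask.any():
            raise ValueError(f"predictor '{col}' is entirely missing; "
                             "cannot compute an imputation mean")
        means[col] = float(vals[mask].mean())
    return means


def impute(features: pd.DataFrame,
           imputation_means: dict[str, float]) -> pd.DataFrame:
    """Fill missing numeric values with the supplied means.

    Non-missing values are untouched; a mean for a column absent from the
    table is ignored with a warning. Idempotent.
    """
    out = features.copy()
    for col, mean in imputation_means.items():
        if col not in out.columns:
            logger.warning("imputation mean for unknown predictor '%s' ignored",
                           col)
            continue
        out[col] = out[col].fillna(mean)
    return out
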