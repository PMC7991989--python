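"""The rule-of-thumb used at the bedside: three raised readings in a row.

Current practice flags a woman for possible treatment escalation when 3 or
more consecutive readings of the same meal tag are over that tag's
designated threshold. "Consecutive" means consecutive occurrences of the
tag in time order (typically consecutive days), regardless of calendar
gaps, and "over" is a strict inequality — a reading exactly at the
threshold does not count. Unlike a score-based model, the rule yields a
single fixed operating point in ROC space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HeuristicDecision:
    """Outcome of the 3-in-a-row rule on one evaluation span."""

    positive: bool
    triggering_tag: str | None = None
    trigger_date: pd.Timestamp | None = None

    def __post_init__(self):
        if self.positive != (self.triggering_tag is not None):
            raise ValueError("positive iff a triggering tag is present")


def heuristic_classify(readings: pd.DataFrame,
                       thresholds: dict[str, float],
                       run_length: int = 3) -> HeuristicDecision:
    """Apply the consecutive-raised-readings rule to one span of readings.

    For each tag, readings are taken in time order; the decision is
    positive iff some tag shows ``run_length`` consecutive values strictly
    above that tag's threshold. The earliest completed run (by the
    timestamp of its final reading) determines the triggering tag and
    trigger date.
    """
    best_time, best_tag = None, None
    if len(readings):
        for tag, grp in readings.groupby("meal_tag"):
            if tag not in thresholds:
                continue
            grp = grp.sort_values("timestamp", kind="mergesort")
            over = (grp["bg_mmol"].to_numpy(float) > thresholds[tag])
            times = grp["timestamp"].to_numpy()
            run = 0
            for i, flag in enumerate(over):
                run = run + 1 if flag else 0
                if run >= run_length:
                    t = times[i]
                    if best_time is None or t < best_time:
                        best_time, best_tag = t, tag
                    break
    if best_tag is None:
        return HeuristicDecision(False)
    return HeuristicDecision(True, best_tag, pd.Timestamp(best_time))


def heuristic_operating_point(window_table: pd.DataFrame
                              ) -> tuple[float, float]:
    """(FPR, TPR) of the rule over a set of labeled evaluation windows.

    ``window_table`` must carry ``label`` and a 0/1 ``heuristic_positive``
    column (one decision per window, as produced by the window builder).
    TPR is the flagged fraction of diet-drug windows, FPR the flagged
    fraction of diet-diet windows; either is NaN when its class is absent.
    """
    pos = window_table["label"] == "diet_drug"
    flagged = window_table["heuristic_positive"].astype(bool)
    tpr = float(flagged[pos].mean()) if pos.any() else np.nan
    fpr = float(flagged[~pos].mean()) if (~pos).any() else np.nan
    return fpr, tpr
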