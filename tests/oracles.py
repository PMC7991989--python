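"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive pure-Python code paths: explicit loops, the stdlib
``statistics`` module, and exhaustive enumeration. They share no code with
the package.
"""

import math
import statistics

from gdm_escalation.schema import MEAL_TAGS, RISK_FLAGS, TAG_FAMILIES
from gdm_escalation.windows import RAISED_TAGS


def brute_force_auc(scores, labels):
    """Pairwise counting: P(s+ > s-) with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return math.nan
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_runs(flags, run_length=3):
    """Count of all length-``run_length`` all-True windows."""
    return sum(
        all(flags[i + j] for j in range(run_length))
        for i in range(len(flags) - run_length + 1)
    )


def brute_force_heuristic_positive(rows, thresholds, run_length=3):
    """Scan every length-3 subsequence of same-tag readings in time order.

    ``rows`` is a list of (timestamp, tag, value) tuples.
    """
    for tag in {t for _, t, _ in rows}:
        seq = sorted([(ts, v) for ts, t, v in rows if t == tag])
        for i in range(len(seq) - run_length + 1):
            if all(seq[i + j][1] > thresholds[tag] for j in range(run_length)):
                return True
    return False


def _slope(ts, vs):
    if len(vs) < 2 or max(ts) == min(ts):
        return math.nan
    tbar = statistics.fmean(ts)
    vbar = statistics.fmean(vs)
    num = sum((t - tbar) * (v - vbar) for t, v in zip(ts, vs))
    den = sum((t - tbar) ** 2 for t in ts)
    return num / den


def _stats(prefix, ts, vs, out, with_sd_slope=True):
    if vs:
        out[f"{prefix}_mean"] = statistics.fmean(vs)
        out[f"{prefix}_min"] = min(vs)
        out[f"{prefix}_max"] = max(vs)
    else:
        out[f"{prefix}_mean"] = math.nan
        out[f"{prefix}_min"] = math.nan
        out[f"{prefix}_max"] = math.nan
    if with_sd_slope:
        out[f"{prefix}_sd"] = statistics.stdev(vs) if len(vs) >= 2 else math.nan
        out[f"{prefix}_slope"] = _slope(ts, vs)


def naive_features(window, readings, demo, thresholds):
    """Recompute the full window feature vector the slow way."""
    rows = []
    for r in readings.itertuples():
        if r.patient_id != window.patient_id:
            continue
        if window.start <= r.timestamp < window.end:
            t = (r.timestamp - window.start).total_seconds() / 86400.0
            rows.append((t, r.meal_tag, float(r.bg_mmol)))
    out = {}
    for fam, fam_tags in TAG_FAMILIES.items():
        sel = [(t, v) for t, tag, v in rows if tag in fam_tags]
        _stats(fam, [t for t, _ in sel], [v for _, v in sel], out)
    for tag in MEAL_TAGS:
        sel = [v for _, tg, v in rows if tg == tag]
        _stats(tag.replace("-", "_"), [], sel, out, with_sd_slope=False)
    for tag in RAISED_TAGS:
        flags = [False] * 7
        for t, tg, v in rows:
            if tg == tag and v > thresholds[tag] and 0 <= int(t) < 7:
                flags[int(t)] = True
        out[f"raised3_{tag.replace('-', '_')}"] = brute_force_runs(flags)
    out["age"] = float(demo["age"])
    out["bmi"] = float(demo["bmi"])
    out["ethnicity_risk"] = float(demo["ethnicity_risk"])
    for flag in RISK_FLAGS:
        out[flag] = float(demo[flag])
    return out
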