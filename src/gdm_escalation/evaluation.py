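"""Repeated-holdout evaluation: ROC/AUC percentile bands and summaries.

The experiment is repeated over (by default) 100 random patient-level
70/30 splits. Each repetition trains the full recipe — window choice for
diet-diet patients, majority-class downsampling, elastic-net selection,
unpenalized logistic refit — on its training patients and scores every
validation window of the held-out patients (diet-diet patients contribute
all their non-overlapping weeks, diet-drug patients their single
pre-medication window; the validation set keeps the natural class
imbalance). Per-repetition ROC, AUC, precision-recall and the clinical
heuristic's operating point are recorded and summarized by 5/50/95
percentiles: ROC bands are taken vertically (TPR percentiles on a common
FPR grid with 0.01 spacing), and AUC by its empirical percentiles and
histogram.

Splits are at the patient level and stratified by group, so no woman ever
contributes windows to both sides of a split. All randomness derives from
one master seed; a full run is reproducible bit for bit.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve

from .heuristic import heuristic_operating_point
from .model import (
    FittedModel,
    downsample_majority,
    fit_logistic,
    predict_scores,
    select_features,
)
from .preprocess import fit_imputation_means, impute
from .windows import META_COLUMNS

logger = logging.getLogger(__name__)

FPR_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
PERCENTILES = (5, 50, 95)


@dataclass
class EvalConfig:
    n_reps: int = 100
    train_frac: float = 0.7
    alpha: float = 0.75
    cv_folds: int = 5
    selection_rule: str = "min"
    fit_on: str = "all_population"
    seed: int = 0


@dataclass
class RepResult:
    """Everything recorded for one repetition."""

    seed: int
    train_patients: list[str] = field(default_factory=list)
    val_patients: list[str] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    auc: float = np.nan
    fpr: np.ndarray | None = None
    tpr: np.ndarray | None = None
    precision: np.ndarray | None = None
    recall: np.ndarray | None = None
    heuristic_fpr: float = np.nan
    heuristic_tpr: float = np.nan
    scores: np.ndarray | None = None
    y_true: np.ndarray | None = None
    model: FittedModel | None = None
    failed: bool = False
    error: str | None = None


@dataclass
class RepeatedEvalResult:
    reps: list[RepResult]
    n_failures: int
    summary: dict
    config: EvalConfig


class EvaluationError(ValueError):
    pass


def split_patients(patient_labels: pd.DataFrame, train_frac: float,
                   rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Patient-level split, stratified by group; disjoint and exhaustive.

    ``patient_labels`` has one row per patient with ``patient_id`` and
    ``label``. Each class needs at least 2 patients so both sides of the
    split contain it.
    """
    train: list[str] = []
    val: list[str] = []
    for label, grp in patient_labels.groupby("label", sort=True):
        ids = np.sort(grp["patient_id"].to_numpy(object))
        n = len(ids)
        if n < 2:
            raise EvaluationError(
                f"class '{label}' has {n} patient(s); need at least 2 to split"
            )
        n_train = int(round(train_frac * n))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        train += list(ids[perm[:n_train]])
        val += list(ids[perm[n_train:]])
    return sorted(train), sorted(val)


def auc_score(scores, y_true) -> float:
    """Pairwise (Mann-Whitney) AUC: P(score+ > score-) + half-credit ties.

    NaN-flagged when either class is absent.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    from scipy.stats import rankdata

    ranks = rankdata(s)
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def roc_points(scores, y_true) -> tuple[np.ndarray, np.ndarray]:
    """Full ROC polyline anchored at (0,0) and (1,1).

    Thresholds sweep every distinct score; the trapezoidal area under the
    returned points equals :func:`auc_score` exactly.
    """
    y = np.asarray(y_true, dtype=int)
    if y.sum() in (0, len(y)):
        raise EvaluationError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, float),
                            drop_intermediate=False)
    return fpr, tpr


def pr_points(scores, y_true) -> tuple[np.ndarray, np.ndarray]:
    """(precision, recall) points, recall increasing."""
    precision, recall, _ = precision_recall_curve(
        np.asarray(y_true, int), np.asarray(scores, float)
    )
    return precision[::-1], recall[::-1]


def tpr_at_fpr(fpr: np.ndarray, tpr: np.ndarray, target: float) -> float:
    """Step-function TPR of an ROC at a given FPR (max TPR with FPR <= target)."""
    idx = np.searchsorted(fpr, target, side="right") - 1
    return float(tpr[idx]) if idx >= 0 else 0.0


def _interp_precision(precision: np.ndarray, recall: np.ndarray,
                      grid: np.ndarray) -> np.ndarray:
    """Interpolated precision: max precision at recall >= each grid point."""
    order = np.argsort(recall)
    r, p = recall[order], precision[order]
    # running max of precision from the high-recall end
    p_env = np.maximum.accumulate(p[::-1])[::-1]
    idx = np.searchsorted(r, grid, side="left")
    out = np.zeros_like(grid, dtype=float)
    ok = idx < len(r)
    out[ok] = p_env[idx[ok]]
    return out


def run_repeated_experiment(window_table: pd.DataFrame,
                            config: EvalConfig) -> RepeatedEvalResult:
    """Run the full repeated-holdout experiment on a window feature table.

    A repetition that raises is recorded as failed and the run continues;
    the failure count is reported in the result.
    """
    feature_cols = [c for c in window_table.columns if c not in META_COLUMNS]
    patient_labels = (
        window_table[["patient_id", "label"]].drop_duplicates()
        .reset_index(drop=True)
    )
    present = set(patient_labels["label"])
    for cls in ("diet_diet", "diet_drug"):
        if cls not in present:
            raise EvaluationError(
                f"class '{cls}' is absent from the cohort; cannot evaluate"
            )
    global_means = None
    if config.fit_on == "all_population":
        global_means = fit_imputation_means(window_table[feature_cols])

    master = np.random.default_rng(config.seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=config.n_reps)
    reps: list[RepResult] = []
    for rep_seed in rep_seeds:
        rep = RepResult(seed=int(rep_seed))
        try:
            _run_one(rep, window_table, patient_labels, feature_cols,
                     global_means, config)
        except Exception as exc:  # noqa: BLE001 - record and continue
            logger.warning("repetition with seed %d failed: %s", rep.seed, exc)
            rep.failed = True
            rep.error = str(exc)
        reps.append(rep)
    n_failures = sum(r.failed for r in reps)
    if n_failures == config.n_reps:
        raise EvaluationError("every repetition failed; see log")
    summary = summarize(reps)
    return RepeatedEvalResult(reps=reps, n_failures=n_failures,
                              summary=summary, config=config)


def _run_one(rep: RepResult, table: pd.DataFrame,
             patient_labels: pd.DataFrame, feature_cols: list[str],
             global_means, config: EvalConfig) -> None:
    rng = np.random.default_rng(rep.seed)
    train_ids, val_ids = split_patients(patient_labels, config.train_frac, rng)
    rep.train_patients, rep.val_patients = train_ids, val_ids

    # One training window per training patient: the canonical window for
    # diet-drug, a uniformly drawn week for diet-diet.
    ttab = table[table["patient_id"].isin(train_ids)]
    picked = []
    for _, grp in ttab.groupby("patient_id", sort=True):
        if grp["label"].iloc[0] == "diet_drug":
            picked.append(grp.index[0])
        else:
            picked.append(grp.index[int(rng.integers(len(grp)))])
    train_rows = table.loc[picked]

    means = global_means
    if means is None:  # train_only mode: refit on this split's training rows
        means = fit_imputation_means(train_rows[feature_cols])

    balanced = downsample_majority(train_rows, rng)
    X_train = impute(balanced[feature_cols], means)
    y_train = (balanced["label"] == "diet_drug").to_numpy(int)

    sel_seed = int(rng.integers(0, 2**31 - 1))
    rep.selected = select_features(
        X_train, y_train, alpha=config.alpha, folds=config.cv_folds,
        seed=sel_seed, rule=config.selection_rule,
    )

    val_rows = table[table["patient_id"].isin(val_ids)]
    X_val = impute(val_rows[feature_cols], means)
    y_val = (val_rows["label"] == "diet_drug").to_numpy(int)

    if rep.selected:
        rep.model = fit_logistic(X_train, y_train, rep.selected,
                                 alpha=config.alpha, folds=config.cv_folds,
                                 seed=sel_seed)
        scores = predict_scores(rep.model, X_val)
    else:
        # nothing survived the penalty: uninformative constant score
        scores = np.full(len(val_rows), 0.5)

    rep.scores, rep.y_true = scores, y_val
    rep.auc = auc_score(scores, y_val)
    rep.fpr, rep.tpr = roc_points(scores, y_val)
    rep.precision, rep.recall = pr_points(scores, y_val)
    rep.heuristic_fpr, rep.heuristic_tpr = heuristic_operating_point(val_rows)


def summarize(reps: list[RepResult]) -> dict:
    """5/50/95-percentile summaries over the successful repetitions."""
    ok = [r for r in reps if not r.failed]
    if not ok:
        raise EvaluationError("no successful repetitions to summarize")
    aucs = np.array([r.auc for r in ok])
    tpr_mat = np.stack([
        np.array([tpr_at_fpr(r.fpr, r.tpr, g) for g in FPR_GRID]) for r in ok
    ])
    roc_bands = {
        f"p{p}": np.percentile(tpr_mat, p, axis=0).tolist() for p in PERCENTILES
    }
    recall_grid = FPR_GRID
    prec_mat = np.stack([
        _interp_precision(r.precision, r.recall, recall_grid) for r in ok
    ])
    pr_bands = {
        f"p{p}": np.percentile(prec_mat, p, axis=0).tolist()
        for p in PERCENTILES
    }
    hist_counts, hist_edges = np.histogram(aucs, bins=20, range=(0.0, 1.0))
    freq = Counter()
    for r in ok:
        freq.update(r.selected)
    selection_frequencies = dict(
        sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    heur_fpr = np.array([r.heuristic_fpr for r in ok])
    heur_tpr = np.array([r.heuristic_tpr for r in ok])
    model_tpr_at_heur = np.array([
        tpr_at_fpr(r.fpr, r.tpr, r.heuristic_fpr) for r in ok
    ])
    return {
        "n_reps": len(reps),
        "n_successful": len(ok),
        "auc_percentiles": {
            f"p{p}": float(np.percentile(aucs, p)) for p in PERCENTILES
        },
        "auc_mean": float(aucs.mean()),
        "auc_sd": float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        "auc_histogram": {
            "counts": hist_counts.tolist(),
            "bin_edges": hist_edges.tolist(),
        },
        "fpr_grid": FPR_GRID.tolist(),
        "roc_tpr_percentiles": roc_bands,
        "recall_grid": recall_grid.tolist(),
        "pr_precision_percentiles": pr_bands,
        "selection_frequencies": selection_frequencies,
        "n_selected_median": float(np.median([len(r.selected) for r in ok])),
        "heuristic": {
            "fpr_median": float(np.nanmedian(heur_fpr)),
            "tpr_median": float(np.nanmedian(heur_tpr)),
            "model_tpr_at_heuristic_fpr_median": float(
                np.median(model_tpr_at_heur)
            ),
            "model_tpr_minus_heuristic_tpr_mean": float(
                np.nanmean(model_tpr_at_heur - heur_tpr)
            ),
        },
    }


def score_distributions(result: RepeatedEvalResult, bins: int = 20) -> dict:
    """Per-class score histograms of the repetition nearest the median AUC.

    Also reports that model's selected feature list — the analogue of
    inspecting one representative model's scores and its (typically few)
    surviving predictors.
    """
    ok = [r for r in result.reps if not r.failed]
    if not ok:
        raise EvaluationError("no successful repetitions")
    aucs = np.array([r.auc for r in ok])
    median = np.median(aucs)
    rep = ok[int(np.argmin(np.abs(aucs - median)))]
    edges = np.linspace(0.0, 1.0, bins + 1)
    pos = rep.scores[rep.y_true == 1]
    neg = rep.scores[rep.y_true == 0]
    return {
        "rep_seed": rep.seed,
        "rep_auc": float(rep.auc),
        "median_auc": float(median),
        "selected_predictors": list(rep.selected),
        "n_features": len(rep.selected),
        "bin_edges": edges.tolist(),
        "counts_diet_drug": np.histogram(pos, bins=edges)[0].tolist(),
        "counts_diet_diet": np.histogram(neg, bins=edges)[0].tolist(),
    }
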