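"""Class-balanced training: downsample, select by elastic net, fit, score.

Training follows a two-step recipe. The over-represented diet-diet class
is first randomly downsampled to the size of the diet-drug class (the
validation set is never downsampled, preserving the natural imbalance
there). An elastic-net-penalized logistic regression with mixing parameter
``alpha = 0.75`` is then fitted over a geometric penalty path, the penalty
strength chosen by 5-fold cross-validated deviance, and the predictors
with nonzero coefficients at that penalty are retained. Finally an
unpenalized logistic model is refitted on the selected predictors; its
inverse-logit linear score in [0, 1] is the model output.

Predictors are standardized (zero mean, unit SD on the training rows)
before penalization, and the standardization is stored and reapplied at
prediction time, so scores are invariant to affine rescaling of any
predictor. The penalty is chosen at the cross-validated minimum by
default; the more conservative one-standard-error rule is available.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

#: Geometric grid of inverse penalty strengths for the elastic-net path.
DEFAULT_CS = np.logspace(-2.5, 1.5, 12)

#: |coefficient| above which (on standardized predictors) an unpenalized
#: logistic fit is treated as separated and refitted with a weak ridge.
SEPARATION_COEF_LIMIT = 15.0


class ModelError(ValueError):
    pass


def downsample_majority(features: pd.DataFrame, rng: np.random.Generator,
                        label_col: str = "label") -> pd.DataFrame:
    """Subsample the majority class to the minority count, w/o replacement.

    Minority rows pass through untouched; raises if either class is
    absent. Deterministic for a fixed generator state.
    """
    counts = features[label_col].value_counts()
    if len(counts) < 2:
        raise ModelError(
            f"both classes required for downsampling; got {dict(counts)}"
        )
    minority = counts.idxmin()
    majority = counts.idxmax()
    if counts[minority] == counts[majority]:
        return features.copy()
    maj_idx = features.index[features[label_col] == majority].to_numpy()
    keep = rng.choice(maj_idx, size=int(counts[minority]), replace=False)
    kept = np.concatenate([
        features.index[features[label_col] == minority].to_numpy(), keep
    ])
    return features.loc[np.sort(kept)]


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant predictors pass through centred
    return mean, scale


def select_features(X: pd.DataFrame, y, alpha: float = 0.75, folds: int = 5,
                    seed: int = 0, rule: str = "min",
                    Cs: np.ndarray | None = None) -> list[str]:
    """Predictors with nonzero elastic-net coefficients at the CV-chosen penalty.

    ``X`` must be complete (post-imputation). The penalty path is fitted
    per fold with warm starts; the deviance (log-loss) on the held-out
    fold selects the penalty — its minimum under ``rule='min'``, or the
    strongest penalty within one standard error of the minimum under
    ``rule='1se'``. Zero-variance-everywhere input yields an empty
    selection with a warning.
    """
    if Cs is None:
        Cs = DEFAULT_CS
    names = list(X.columns)
    Xm = X.to_numpy(float)
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ModelError("feature selection requires both classes")
    if np.all(Xm.std(axis=0) == 0):
        logger.warning("all predictors have zero variance; empty selection")
        return []
    mean, scale = _standardize_fit(Xm)
    Z = (Xm - mean) / scale

    # stratified CV needs every fold to contain both classes
    min_class = int(np.bincount(yv).min())
    if min_class < 2:
        raise ModelError("need at least 2 rows per class for cross-validation")
    folds = min(folds, min_class)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(Cs)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for f, (tr, va) in enumerate(cv.split(Z, yv)):
            est = LogisticRegression(
                solver="saga", l1_ratio=alpha,
                warm_start=True, max_iter=3000, tol=1e-4,
            )
            for j, c in enumerate(Cs):  # strong -> weak penalty, warm-started
                est.C = float(c)
                est.fit(Z[tr], yv[tr])
                p = est.predict_proba(Z[va])[:, 1]
                dev[f, j] = log_loss(yv[va], p, labels=[0, 1])
        mean_dev = dev.mean(axis=0)
        j_min = int(np.argmin(mean_dev))
        if rule == "1se":
            se = dev[:, j_min].std(ddof=1) / np.sqrt(folds)
            ok = np.nonzero(mean_dev <= mean_dev[j_min] + se)[0]
            j_pick = int(ok[0])  # smallest C on the grid = strongest penalty
        elif rule == "min":
            j_pick = j_min
        else:
            raise ModelError("rule must be 'min' or '1se'")
        final = LogisticRegression(
            solver="saga", l1_ratio=alpha,
            C=float(Cs[j_pick]), max_iter=5000, tol=1e-4,
        ).fit(Z, yv)
    coef = final.coef_.ravel()
    return [n for n, c in zip(names, coef) if abs(c) > 1e-8]


@dataclass
class FittedModel:
    """An unpenalized logistic model on the selected, standardized predictors."""

    selected_predictors: list[str]
    coefficients: list[float]
    intercept: float
    standardize_mean: list[float]
    standardize_scale: list[float]
    selection_alpha: float = 0.75
    cv_folds: int = 5
    training_seed: int = 0
    ridge_fallback: bool = False
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.__dict__, indent=2, default=float)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def fit_logistic(X: pd.DataFrame, y, selected: list[str] | None = None,
                 alpha: float = 0.75, folds: int = 5,
                 seed: int = 0) -> FittedModel:
    """Maximum-likelihood logistic fit on the selected predictors.

    Under (quasi-)complete separation the unpenalized likelihood diverges;
    detected via an implausibly large standardized coefficient, in which
    case the fit falls back to a weak ridge penalty and the model record
    is flagged.
    """
    if selected is None:
        selected = list(X.columns)
    if not selected:
        raise ModelError("at least one selected predictor is required")
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ModelError("both classes required to fit")
    Xm = X[selected].to_numpy(float)
    mean, scale = _standardize_fit(Xm)
    Z = (Xm - mean) / scale
    ridge = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est = LogisticRegression(C=np.inf, solver="lbfgs",
                                 max_iter=2000).fit(Z, yv)
        # every training row strictly correctly classified => the MLE
        # diverges (complete separation); huge coefficients => quasi-complete
        separated = (est.predict(Z) == yv).all() or \
            np.abs(est.coef_).max() > SEPARATION_COEF_LIMIT
        if separated:
            logger.warning(
                "separation suspected (|coef| %.1f); refitting with weak ridge",
                float(np.abs(est.coef_).max()),
            )
            est = LogisticRegression(C=100.0, solver="lbfgs",
                                     max_iter=2000).fit(Z, yv)
            ridge = True
    return FittedModel(
        selected_predictors=list(selected),
        coefficients=[float(c) for c in est.coef_.ravel()],
        intercept=float(est.intercept_[0]),
        standardize_mean=[float(m) for m in mean],
        standardize_scale=[float(s) for s in scale],
        selection_alpha=alpha,
        cv_folds=folds,
        training_seed=seed,
        ridge_fallback=ridge,
    )


def predict_scores(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Inverse-logit scores in [0, 1] using the stored standardization."""
    missing = [p for p in model.selected_predictors if p not in X.columns]
    if missing:
        raise ModelError(f"missing predictor column(s) {missing}")
    Xm = X[model.selected_predictors].to_numpy(float)
    Z = (Xm - np.asarray(model.standardize_mean)) / np.asarray(
        model.standardize_scale)
    eta = Z @ np.asarray(model.coefficients) + model.intercept
    return expit(eta)
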