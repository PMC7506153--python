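"""Logistic staging model, radscore, ROC/cutoff metrics and calibration.

The staging model is an unpenalized maximum-likelihood logistic regression
on the selected (standardized) features.  Its linear predictor is the
per-subject *radscore*; diagnostic reporting uses the empirical ROC curve
(trapezoid AUC, equivalent to Mann-Whitney with 1/2 credit for ties), a
radscore cutoff maximizing Youden's J, and an equal-width-bin calibration
curve with a least-squares fitted line.  One fitted model serves both the
training and testing reports; the evaluation API takes the frozen model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

log = logging.getLogger(__name__)

__all__ = ["StageModel", "DiagnosticReport", "fit_logistic", "radscore",
           "roc_analysis", "choose_cutoff", "calibration_curve", "evaluate"]


@dataclass(frozen=True)
class StageModel:
    intercept: float
    coefficients: pd.Series           # per selected feature
    modality: str = ""
    cutoff: float | None = None       # training radscore cutoff, set after fit

    def with_cutoff(self, cutoff: float) -> "StageModel":
        return StageModel(self.intercept, self.coefficients, self.modality,
                          float(cutoff))


@dataclass
class DiagnosticReport:
    cohort: str                       # "train" or "test"
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    cutoff: float                     # cutoff used for the headline metrics
    cohort_cutoff: float              # Youden-optimal cutoff on this cohort
    roc_points: pd.DataFrame          # columns fpr, tpr, threshold
    calibration_bins: pd.DataFrame    # columns mean_predicted, observed, n
    calibration_slope: float
    calibration_intercept: float


def fit_logistic(train: pd.DataFrame, labels: pd.Series,
                 modality: str = "") -> StageModel:
    """Unpenalized ML logistic fit; ridge-stabilized on perfect separation.

    Separation is detected by non-convergence or runaway coefficients, in
    which case the model is refit with a vanishing L2 penalty (1e-6) and a
    warning is logged.
    """
    y = pd.Series(labels).reindex(train.index).to_numpy().astype(int)
    X = train.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in the staging feature matrix")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf = LogisticRegression(C=np.inf, solver="lbfgs",
                                 max_iter=200, tol=1e-10)
        clf.fit(X, y)
    unstable = (any(issubclass(w.category, ConvergenceWarning) for w in caught)
                or np.abs(clf.coef_).max() > 30.0)
    if unstable:
        log.warning("fit_logistic: separation suspected; refitting with "
                    "ridge penalty 1e-6")
        n = len(y)
        clf = LogisticRegression(l1_ratio=0.0, C=1.0 / (1e-6 * n),
                                 solver="lbfgs", max_iter=2000, tol=1e-10)
        clf.fit(X, y)
    return StageModel(
        intercept=float(clf.intercept_[0]),
        coefficients=pd.Series(clf.coef_[0], index=train.columns),
        modality=modality,
    )


def radscore(model: StageModel, features: pd.DataFrame) -> pd.Series:
    """Linear predictor ``intercept + sum_i beta_i x_i`` per subject."""
    missing = [c for c in model.coefficients.index if c not in features.columns]
    if missing:
        raise KeyError(f"features missing for radscore: {missing}")
    X = features[model.coefficients.index].to_numpy(dtype=float)
    scores = model.intercept + X @ model.coefficients.to_numpy()
    return pd.Series(scores, index=features.index, name="radscore")


def roc_analysis(scores, labels) -> tuple[float, pd.DataFrame]:
    """Empirical ROC over all score thresholds and its trapezoid AUC."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, points


@dataclass(frozen=True)
class CutoffMetrics:
    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float
    youden_j: float


def _metrics_at(scores: np.ndarray, y: np.ndarray, cutoff: float) -> CutoffMetrics:
    pred = scores >= cutoff
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec = float((~pred[neg]).mean()) if neg.any() else np.nan
    acc = float((pred == (y == 1)).mean())
    return CutoffMetrics(float(cutoff), acc, sens, spec, sens + spec - 1.0)


def choose_cutoff(scores, labels) -> CutoffMetrics:
    """Radscore cutoff maximizing Youden's J over the observed scores.

    Predicted-positive means score >= cutoff; J ties resolve to the lower
    cutoff.  An optimum with AUC below 0.5 (inverted orientation) is logged.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to choose a cutoff")
    best: CutoffMetrics | None = None
    for c in np.unique(s):  # ascending: lower cutoff wins ties
        m = _metrics_at(s, y, c)
        if best is None or m.youden_j > best.youden_j + 1e-12:
            best = m
    auc, _ = roc_analysis(s, y)
    if auc < 0.5:
        log.warning("choose_cutoff: AUC %.3f < 0.5 — score orientation "
                    "appears inverted", auc)
    return best


def calibration_curve(probabilities, labels, bins: int = 10
                      ) -> tuple[pd.DataFrame, float, float]:
    """Equal-width probability bins with (mean predicted, observed fraction),
    and a least-squares line through the nonempty bin points.

    Returns ``(bin_table, slope, intercept)``; the line is NaN when fewer
    than two bins are nonempty.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        in_bin = idx == b
        if in_bin.any():
            rows.append({"bin": b,
                         "mean_predicted": float(p[in_bin].mean()),
                         "observed": float(y[in_bin].mean()),
                         "n": int(in_bin.sum())})
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        slope, intercept = np.polyfit(table["mean_predicted"],
                                      table["observed"], 1)
    else:
        log.warning("calibration_curve: fewer than 2 nonempty bins; "
                    "fitted line undefined")
        slope = intercept = np.nan
    return table, float(slope), float(intercept)


def evaluate(model: StageModel, features: pd.DataFrame, labels: pd.Series,
             cohort: str, cutoff: float | None = None,
             calibration_bins: int = 10) -> DiagnosticReport:
    """Diagnostic report of a frozen model on one cohort.

    Headline accuracy/sensitivity/specificity use ``cutoff`` when given
    (typically the training cutoff); the cohort's own Youden-optimal cutoff
    is reported alongside.
    """
    y = pd.Series(labels).reindex(features.index)
    scores = radscore(model, features)
    auc, points = roc_analysis(scores, y)
    own = choose_cutoff(scores, y)
    use = own.cutoff if cutoff is None else float(cutoff)
    m = _metrics_at(scores.to_numpy(), y.to_numpy().astype(int), use)
    probs = 1.0 / (1.0 + np.exp(-scores.to_numpy()))
    bins, slope, intercept = calibration_curve(probs, y, calibration_bins)
    return DiagnosticReport(
        cohort=cohort, auc=auc, accuracy=m.accuracy,
        sensitivity=m.sensitivity, specificity=m.specificity,
        cutoff=use, cohort_cutoff=own.cutoff, roc_points=points,
        calibration_bins=bins, calibration_slope=slope,
        calibration_intercept=intercept,
    )
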