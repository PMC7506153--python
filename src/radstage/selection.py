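"""Feature cleaning, cohort splitting, mRMR ranking and LASSO selection.

The selection chain mirrors a standard radiomics signature workflow: a
stratified 7:3 train/test split; per-feature outlier replacement (training
values beyond |z| > 3 replaced by the mean of the inliers) followed by
z-score standardization with training statistics only; greedy
minimum-redundancy-maximum-relevance ranking down to 20 features (MID
variant, mutual information after 10-quantile discretization); and an
L1-penalized logistic regression over a 50-point log-spaced penalty grid,
with the penalty chosen by 10-fold cross-validated misclassification error
(minimum rule).  Test-set rows never influence any of these steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

__all__ = ["split_cohort", "clean_features", "CleanedTable",
           "mrmr_rank", "lasso_select", "SelectionResult"]


# ---------------------------------------------------------------------------
# split

def split_cohort(labels: pd.Series, train_fraction: float = 0.7,
                 seed: int = 0) -> pd.Series:
    """Stratified train/test assignment; returns 'train'/'test' per subject.

    The total training size rounds to the nearest subject; per-class counts
    are allocated by largest remainder so class balance is preserved.
    """
    if not (0 < train_fraction < 1):
        raise ValueError(f"train fraction must be in (0, 1), got {train_fraction}")
    labels = pd.Series(labels)
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("both stage classes must be present to split")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 subjects")
    n_train_total = int(round(len(labels) * train_fraction))
    sizes = {c: (labels == c).sum() for c in classes}
    raw = {c: sizes[c] * train_fraction for c in classes}
    base = {c: int(np.floor(raw[c])) for c in classes}
    short = n_train_total - sum(base.values())
    by_remainder = sorted(classes, key=lambda c: raw[c] - base[c], reverse=True)
    for c in by_remainder[:short]:
        base[c] += 1
    rng = np.random.default_rng(seed)
    assign = pd.Series("test", index=labels.index, name="split")
    for c in classes:
        idx = labels.index[labels == c].to_numpy()
        picked = rng.permutation(len(idx))[: base[c]]
        assign.loc[idx[picked]] = "train"
    return assign


# ---------------------------------------------------------------------------
# cleaning

@dataclass
class CleanedTable:
    """Standardized feature table plus the training statistics that made it."""

    table: pd.DataFrame                  # all subjects, standardized
    train_mean: pd.Series
    train_sd: pd.Series
    dropped: list[str] = field(default_factory=list)
    outlier_log: dict[str, int] = field(default_factory=dict)

    def train_rows(self, split: pd.Series) -> pd.DataFrame:
        return self.table.loc[split.reindex(self.table.index) == "train"]

    def test_rows(self, split: pd.Series) -> pd.DataFrame:
        return self.table.loc[split.reindex(self.table.index) == "test"]


def clean_features(table: pd.DataFrame, split: pd.Series,
                   outlier_z: float = 3.0) -> CleanedTable:
    """Outlier replacement and z-score standardization, trained on the
    training split only.

    Per feature: training values with |z| > ``outlier_z`` (and NaNs) are
    replaced with the mean of the remaining training values; the feature is
    then standardized with the post-replacement training mean and sd, and
    the same affine transform is applied to the test rows.  Zero-variance
    features are dropped with a warning.
    """
    split = split.reindex(table.index)
    if split.isna().any():
        raise ValueError("split assignment missing for some subjects")
    train_idx = split == "train"
    X = table.astype(float).copy()
    dropped: list[str] = []
    outlier_log: dict[str, int] = {}
    means, sds = {}, {}
    for col in list(X.columns):
        tr = X.loc[train_idx, col]
        mu, sd = tr.mean(), tr.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            dropped.append(col)
            continue
        z = (tr - mu) / sd
        bad = z.abs() > outlier_z
        n_bad = int(bad.sum() + tr.isna().sum())
        if n_bad:
            inlier_mean = tr[~bad].mean()
            X.loc[train_idx & (bad.reindex(X.index, fill_value=False)
                               | X[col].isna()), col] = inlier_mean
            outlier_log[col] = n_bad
            tr = X.loc[train_idx, col]
            mu, sd = tr.mean(), tr.std(ddof=0)
            if sd == 0:
                dropped.append(col)
                continue
        # test-side NaNs get the training mean (z = 0)
        X.loc[~train_idx & X[col].isna(), col] = mu
        X[col] = (X[col] - mu) / sd
        means[col], sds[col] = mu, sd
    if dropped:
        log.warning("clean_features: dropped %d zero-variance feature(s): %s",
                    len(dropped), dropped[:5])
        X = X.drop(columns=dropped)
    return CleanedTable(X, pd.Series(means), pd.Series(sds),
                        dropped=dropped, outlier_log=outlier_log)


# ---------------------------------------------------------------------------
# mRMR (MID variant)

def _discretize_feature(x: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-frequency binning; ties collapse bins as needed."""
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="right")


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (bits) of two small integer-coded variables."""
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))


def mrmr_rank(train: pd.DataFrame, labels: pd.Series, keep: int = 20,
              bins: int = 10) -> pd.DataFrame:
    """Greedy MID ranking: maximize MI(f; label) minus the mean MI with the
    already-selected features.

    Returns a DataFrame (one row per kept feature, in selection order) with
    the relevance, mean redundancy and MID score at selection time.  Ties
    break in column (catalog) order.
    """
    if keep > train.shape[1]:
        raise ValueError(f"keep={keep} exceeds feature count {train.shape[1]}")
    y = pd.Series(labels).reindex(train.index).to_numpy()
    y_codes = pd.factorize(y)[0]
    cols = list(train.columns)
    disc = {c: _discretize_feature(train[c].to_numpy(), bins) for c in cols}
    relevance = np.array([_mutual_information(disc[c], y_codes) for c in cols])

    selected: list[int] = []
    red_sum = np.zeros(len(cols))
    rows = []
    available = np.ones(len(cols), dtype=bool)
    for step in range(keep):
        if step == 0:
            scores = relevance.copy()
            red_mean = np.zeros(len(cols))
        else:
            red_mean = red_sum / step
            scores = relevance - red_mean
        scores = np.where(available, scores, -np.inf)
        pick = int(np.argmax(scores))  # first max: catalog-order tie-break
        selected.append(pick)
        available[pick] = False
        rows.append({
            "feature": cols[pick],
            "relevance_bits": float(relevance[pick]),
            "redundancy_bits": float(red_mean[pick]),
            "score": float(scores[pick]),
        })
        d_sel = disc[cols[pick]]
        for k in np.nonzero(available)[0]:
            red_sum[k] += _mutual_information(disc[cols[k]], d_sel)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LASSO-penalized logistic selection

@dataclass
class SelectionResult:
    mrmr_ranking: pd.DataFrame
    lambda_grid: np.ndarray
    cv_error: np.ndarray                  # mean CV misclassification per lambda
    coef_path: np.ndarray                 # (n_lambda, n_features)
    lambda_star: float
    selected_features: list[str]
    coefficients: pd.Series               # at lambda_star, incl. intercept

    def to_dict(self) -> dict:
        return {
            "mrmr_kept": self.mrmr_ranking["feature"].tolist(),
            "lambda_grid": self.lambda_grid.tolist(),
            "cv_error": self.cv_error.tolist(),
            "lambda_star": self.lambda_star,
            "selected_features": self.selected_features,
            "coefficients": self.coefficients.to_dict(),
        }


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # sklearn minimizes  C * sum(logloss) + |w|_1  =>  lambda = 1 / (C * n)
    C = 1.0 / max(lam * X.shape[0], 1e-12)
    clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                             intercept_scaling=1000.0, max_iter=2000,
                             tol=1e-8, random_state=0)
    clf.fit(X, y)
    return clf


def lasso_select(train: pd.DataFrame, labels: pd.Series, folds: int = 10,
                 n_lambda: int = 50, lambda_decades: float = 3.0,
                 seed: int = 0,
                 mrmr_ranking: pd.DataFrame | None = None) -> SelectionResult:
    """L1-penalized logistic selection with cross-validated penalty.

    The grid spans log-uniformly from just above the smallest penalty that
    zeroes every coefficient (``lambda_max``) down ``lambda_decades``
    decades.  The criterion is mean 10-fold stratified misclassification
    error at probability cutoff 0.5; ties prefer the larger (sparser)
    penalty.  Selected features are those with nonzero coefficients at the
    refit on the full training set.
    """
    y = pd.Series(labels).reindex(train.index).to_numpy().astype(int)
    X = train.to_numpy(dtype=float)
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds training size {n}")
    ybar = y.mean()
    lam_max = float(np.abs(X.T @ (y - ybar)).max() / n)
    grid = np.logspace(np.log10(lam_max * 1.05),
                       np.log10(lam_max * 1.05) - lambda_decades, n_lambda)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    cv_err = np.zeros(n_lambda)
    for i, lam in enumerate(grid):
        errs = []
        for tr, te in splits:
            clf = _fit_l1(X[tr], y[tr], lam)
            pred = (clf.predict_proba(X[te])[:, 1] >= 0.5).astype(int)
            errs.append(np.mean(pred != y[te]))
        cv_err[i] = np.mean(errs)

    best = int(np.flatnonzero(cv_err == cv_err.min())[0])  # largest lambda wins
    lam_star = float(grid[best])

    coef_path = np.zeros((n_lambda, X.shape[1]))
    for i, lam in enumerate(grid):
        coef_path[i] = _fit_l1(X, y, lam).coef_[0]

    final = _fit_l1(X, y, lam_star)
    coefs = final.coef_[0]
    nz = np.abs(coefs) > 1e-10
    selected = [c for c, keep in zip(train.columns, nz) if keep]
    if not selected:
        log.warning("lasso_select: no nonzero coefficient at lambda* "
                    "(%.4g); empty selection reported", lam_star)
    coefficients = pd.Series(coefs[nz], index=selected)
    coefficients["(intercept)"] = float(final.intercept_[0])
    if mrmr_ranking is None:
        mrmr_ranking = pd.DataFrame({"feature": list(train.columns)})
    return SelectionResult(
        mrmr_ranking=mrmr_ranking,
        lambda_grid=grid,
        cv_error=cv_err,
        coef_path=coef_path,
        lambda_star=lam_star,
        selected_features=selected,
        coefficients=coefficients,
    )
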