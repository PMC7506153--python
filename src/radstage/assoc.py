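"""Association statistics: feature-vs-metabolism correlations and
cohort-comparison tests.

Pearson product-moment correlations (two-sided p from the t transform with
n-2 degrees of freedom) relate each selected radiomic feature to SUVmax,
MTV and TLG across the cohort.  Cohort comparisons between the training and
testing groups use the pooled-variance two-sample t-test for continuous
variables and Pearson's chi-square (no continuity correction) for counts,
with * / ** significance flags at 0.05 / 0.01 and no multiple-testing
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pearson_matrix", "two_sample_t", "two_sample_t_from_raw",
           "chi_square", "compare_cohorts", "stars"]

METABOLIC_COLS = ("suv_max", "mtv_ml", "tlg")


def stars(p: float) -> str:
    """Significance flag: '**' for p < 0.01, '*' for p < 0.05, else ''."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_matrix(features: pd.DataFrame, metabolics: pd.DataFrame
                   ) -> pd.DataFrame:
    """Pearson r and p of each feature against each metabolic parameter.

    Rows are features; per parameter the table carries ``r_<param>``,
    ``p_<param>`` and ``sig_<param>`` columns.  Zero-variance vectors yield
    NaN entries rather than an error.
    """
    common = features.index.intersection(metabolics.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    F = features.loc[common]
    M = metabolics.loc[common]
    rows = {}
    for feat in F.columns:
        x = F[feat].to_numpy(dtype=float)
        row = {}
        for param in METABOLIC_COLS:
            if param not in M.columns:
                continue
            y = M[param].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            row[f"r_{param}"] = r
            row[f"p_{param}"] = p
            row[f"sig_{param}"] = stars(p) if np.isfinite(p) else ""
        rows[feat] = row
    return pd.DataFrame(rows).T


def two_sample_t(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Pooled-variance two-sample t from summary statistics.

    The statistic is ``(mean2 - mean1) / se`` — group 2 minus group 1 — with
    ``n1 + n2 - 2`` degrees of freedom and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0, 1.0
    t = (mean2 - mean1) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def two_sample_t_from_raw(x1, x2) -> tuple[float, float]:
    """Pooled two-sample t from raw vectors; matches the summary form."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return two_sample_t(x1.mean(), x1.std(ddof=1), len(x1),
                        x2.mean(), x2.std(ddof=1), len(x2))


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a counts table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("contingency table must be 2D with nonnegative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


@dataclass
class CohortComparison:
    """Training-vs-testing comparison report, one row per variable."""

    table: pd.DataFrame  # variable, test, statistic, p_value, sig


def compare_cohorts(cohort: pd.DataFrame,
                    metabolics: pd.DataFrame | None = None) -> CohortComparison:
    """Train/test group comparison of demographics and metabolic parameters.

    Continuous variables (age, SUVmax, MTV, TLG) use the pooled t-test
    (testing minus training); gender and stage distributions use Pearson's
    chi-square.
    """
    if "split" not in cohort.columns:
        raise ValueError("cohort table needs a 'split' column")
    df = cohort.copy()
    if metabolics is not None:
        df = df.join(metabolics, how="left")
    tr = df[df["split"] == "train"]
    te = df[df["split"] == "test"]
    if len(tr) == 0 or len(te) == 0:
        raise ValueError("both train and test groups must be nonempty")
    rows = []
    cont = [("age", "age"), ("suv_max", "SUVmax"), ("mtv_ml", "MTV"),
            ("tlg", "TLG")]
    for col, name in cont:
        if col not in df.columns:
            continue
        t, p = two_sample_t_from_raw(tr[col], te[col])
        rows.append({"variable": name, "test": "t", "statistic": t,
                     "p_value": p, "sig": stars(p)})
    for col, name in (("gender", "gender"), ("stage_label", "stage")):
        if col not in df.columns:
            continue
        ct = pd.crosstab(df["split"], df[col])
        chi2, p = chi_square(ct.to_numpy())
        rows.append({"variable": name, "test": "chi2", "statistic": chi2,
                     "p_value": p, "sig": stars(p)})
    return CohortComparison(pd.DataFrame(rows))
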