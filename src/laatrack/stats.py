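"""Cohort-level evaluation statistics for per-case metric tables.

Given a table of per-case strain and mobility summaries with a binary
outcome (thrombus resolved / persisted), this module provides the unpaired
pooled-variance Student t-test, rank-based ROC/AUC with direction handling
(variables inversely related to the outcome are inverted before computing
the c-statistic), and a median split of the cohort by mobility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "unpaired_t_test",
    "roc_auc",
    "median_split",
    "binormal_auc",
    "compare_groups",
    "METRIC_COLUMNS",
]

# metric column -> inversely related to a favourable outcome?
# Minimum strain predicts resolution the *lower* (more negative) it is.
METRIC_COLUMNS = {
    "min_peak_strain_pct": True,
    "max_peak_strain_pct": False,
    "mean_mobility_mm": False,
    "max_mobility_mm": False,
}


def unpaired_t_test(a, b) -> tuple[float, float]:
    """Two-sample pooled-variance (Student) t-test, two-tailed.

    Returns ``(t, p)`` with ``df = n_a + n_b - 2``.  If the pooled variance
    is zero the statistic is degenerate: equal means give ``(0, 1)``,
    unequal means ``(±inf, 0)`` with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; p = 0")
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def roc_auc(scores, labels, invert: bool = False):
    """Rank-based AUC (c-statistic) with the ROC curve points.

    AUC = P(score_pos > score_neg) + 0.5 P(tie).  With ``invert=True`` the
    scores are negated first — used for variables inversely related to the
    outcome so that the reported c-statistic stays above 0.5 for a
    predictive variable.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    s = -scores if invert else scores
    auc = float(roc_auc_score(labels, s))
    fpr, tpr, thresholds = roc_curve(labels, s)
    return auc, np.column_stack([fpr, tpr])


def median_split(values) -> np.ndarray:
    """Split a sample at its median into "lower" / "higher" labels.

    Values strictly above the sample median are "higher"; values at or
    below it are "lower" (ties at the median resolve to "lower").
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    med = np.median(values)
    return np.where(values > med, "higher", "lower")


def binormal_auc(mu_a: float, sd_a: float, mu_b: float, sd_b: float) -> float:
    """Expected AUC of two normal populations: Phi((mu_a-mu_b)/sqrt(sa²+sb²)).

    Closed-form oracle for validating the empirical rank-based AUC on
    simulated cohorts (group a = positives).
    """
    if min(sd_a, sd_b) <= 0:
        raise ValueError("standard deviations must be positive")
    return float(sps.norm.cdf((mu_a - mu_b) / np.hypot(sd_a, sd_b)))


def compare_groups(
    table: pd.DataFrame,
    group_col: str = "group_label",
    positive: str = "responder",
    metrics: dict | None = None,
) -> pd.DataFrame:
    """Group comparison per metric: means, pooled t/p and directed AUC.

    ``table`` needs unique ``case_id``s, a binary ``group_col`` and the
    metric columns; ``metrics`` maps column name -> invert flag (default
    :data:`METRIC_COLUMNS` restricted to the columns present).
    """
    if table["case_id"].duplicated().any():
        raise ValueError("case_ids must be unique")
    metrics = metrics or {
        k: v for k, v in METRIC_COLUMNS.items() if k in table.columns
    }
    groups = table[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {list(groups)}")
    labels = (table[group_col] == positive).astype(int).to_numpy()
    pos = table[labels == 1]
    neg = table[labels == 0]

    rows = []
    for col, invert in metrics.items():
        vals = table[col].to_numpy(dtype=float)
        t, p = unpaired_t_test(pos[col], neg[col])
        auc, _ = roc_auc(vals, labels, invert=invert)
        rows.append(
            {
                "metric": col,
                f"mean_{positive}": float(pos[col].mean()),
                "mean_other": float(neg[col].mean()),
                "t": t,
                "p": p,
                "auc": auc,
                "inverted": invert,
            }
        )
    return pd.DataFrame(rows)
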