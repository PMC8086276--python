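"""Descriptive statistics of the raw panel and pillar correlation analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CorrelationError


def summarize_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-indicator mean, SD (sample form), min, max and missing count.

    Statistics are over observed values only; a fully-missing indicator
    yields NaN statistics (flagged by its missing count), not an exception.
    """
    return pd.DataFrame(
        {
            "mean": panel.mean(skipna=True),
            "sd": panel.std(skipna=True, ddof=1),
            "min": panel.min(skipna=True),
            "max": panel.max(skipna=True),
            "missing": panel.isna().sum(),
        }
    )


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p-values."""

    labels: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame

    def lower_triangle(self) -> pd.DataFrame:
        """r values with the upper triangle blanked (report layout)."""
        mask = np.triu(np.ones(self.r.shape, dtype=bool), k=1)
        return self.r.mask(mask)


def pillar_correlation(
    pillars: pd.DataFrame, alpha: float = 0.05
) -> CorrelationMatrix:
    """Pearson correlation matrix of pillar scores with significance flags.

    p-values come from the exact two-sided t test of zero correlation on
    n - 2 degrees of freedom; ``significant`` marks p < alpha.  Requires at
    least 3 units and non-constant pillar columns.
    """
    if len(pillars) < 3:
        raise CorrelationError("correlation needs at least 3 units")
    constant = [c for c in pillars.columns if pillars[c].nunique() <= 1]
    if constant:
        raise CorrelationError(
            "constant pillar column(s): " + ", ".join(map(str, constant))
        )
    labels = list(pillars.columns)
    k = len(labels)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(pillars.iloc[:, i], pillars.iloc[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=labels, columns=labels)
    p_df = pd.DataFrame(p, index=labels, columns=labels)
    return CorrelationMatrix(
        labels=labels, r=r_df, p=p_df, significant=p_df < alpha
    )
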