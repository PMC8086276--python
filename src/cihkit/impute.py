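"""Hot-deck imputation of missing panel cells.

Each missing cell is filled with the value observed on the most similar
*donor* unit: similarity is Euclidean distance over the z-standardized
indicators observed on both units, so the donated value is always a number
that actually occurs in the column (hot-deck never invents values).  When no
donor is usable the cell falls back to the indicator's reference value
(typically a national average) or, failing that, the column's observed mean.

Imputation is simultaneous: every donor search runs against the original
observed data, so the result does not depend on the order in which cells are
filled, and ties between equidistant donors break on the lexicographically
smallest unit id, making the procedure equivariant under row permutations.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import IndexConfig
from .errors import ImputationError

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ("unit", "indicator", "value", "method", "donor_unit")


class HotDeckImputer(BaseEstimator, TransformerMixin):
    """Nearest-donor hot-deck imputer for units x indicators panels.

    Parameters
    ----------
    reference_values : mapping indicator -> float, optional
        Fallback values used when a missing cell has no usable donor
        (no unit observes the indicator, or the unit shares no observed
        indicator with any donor).
    fallback_to_mean : bool, default True
        When a cell has no donor and no reference value, fall back to the
        column's observed mean (logged) instead of raising.

    Attributes
    ----------
    feature_names_in_ : ndarray of column names seen in ``fit``.
    donor_pool_ : DataFrame, the fit panel (donor candidates).
    means_, stds_ : Series, per-column mean/SD over observed values, used
        to standardize the donor distance.  Zero-SD columns contribute zero
        distance.
    report_ : DataFrame describing every filled cell of the last
        ``transform`` (columns unit, indicator, value, method, donor_unit).
    """

    def __init__(
        self,
        reference_values: Mapping[str, float] | None = None,
        fallback_to_mean: bool = True,
    ):
        self.reference_values = reference_values
        self.fallback_to_mean = fallback_to_mean

    def fit(self, X: pd.DataFrame, y=None) -> "HotDeckImputer":
        X = self._check_frame(X)
        self.feature_names_in_ = np.asarray(X.columns)
        self.donor_pool_ = X.copy()
        self.means_ = X.mean(skipna=True)
        stds = X.std(skipna=True, ddof=0)
        self.stds_ = stds.where(stds > 0, 1.0)  # zero-SD -> zero z-spread
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "donor_pool_"):
            raise ValueError("HotDeckImputer is not fitted")
        X = self._check_frame(X)
        pool = self.donor_pool_
        z_pool = (pool - self.means_) / self.stds_
        z_x = (X - self.means_) / self.stds_
        observed_pool = pool.notna().to_numpy()
        refs = dict(self.reference_values or {})

        out = X.copy()
        records: list[tuple] = []
        pool_ids = list(pool.index)
        zp = z_pool.to_numpy()

        for i, unit in enumerate(X.index):
            row_obs = X.iloc[i].notna().to_numpy()
            if row_obs.all():
                continue
            zi = z_x.iloc[i].to_numpy()
            for j, indicator in enumerate(X.columns):
                if row_obs[j]:
                    continue
                value, method, donor = self._fill_cell(
                    unit, indicator, j, zi, row_obs, zp, observed_pool,
                    pool, pool_ids, refs,
                )
                out.iat[i, j] = value
                records.append((unit, indicator, value, method, donor))

        self.report_ = pd.DataFrame(records, columns=list(REPORT_COLUMNS))
        return out

    def _fill_cell(
        self, unit, indicator, j, zi, row_obs, zp, observed_pool,
        pool, pool_ids, refs,
    ):
        # donor candidates: units (other than the target) observing j
        best_donor = None
        best_key = None
        for d in np.flatnonzero(observed_pool[:, j]):
            donor_id = pool_ids[d]
            if donor_id == unit:
                continue
            shared = row_obs & observed_pool[d]
            shared[j] = False
            if not shared.any():
                continue
            diff = zi[shared] - zp[d][shared]
            dist = float(np.sqrt(np.sum(diff * diff)))
            key = (dist, donor_id)
            if best_key is None or key < best_key:
                best_key = key
                best_donor = donor_id
        if best_donor is not None:
            return float(pool.loc[best_donor, indicator]), "hot_deck", best_donor
        if indicator in refs:
            return float(refs[indicator]), "reference_fallback", None
        col_mean = float(pool[indicator].mean(skipna=True))
        if np.isnan(col_mean) or not self.fallback_to_mean:
            raise ImputationError(
                f"no hot-deck donor and no reference value for indicator "
                f"{indicator!r} (unit {unit!r})"
            )
        logger.warning(
            "no donor and no reference for (%s, %s); using observed column mean",
            unit, indicator,
        )
        return col_mean, "reference_fallback", None

    @staticmethod
    def _check_frame(X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("HotDeckImputer operates on pandas DataFrames")
        return X.astype(float)


def hot_deck_impute(
    panel: pd.DataFrame, config: IndexConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute a panel under a configuration.

    Returns ``(complete_panel, report)`` where the report lists every filled
    cell with its method (``hot_deck`` or ``reference_fallback``) and donor.
    """
    imputer = HotDeckImputer(reference_values=config.reference_values)
    complete = imputer.fit(panel).transform(panel)
    return complete, imputer.report_
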