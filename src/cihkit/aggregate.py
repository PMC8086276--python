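"""Penalized-mean aggregation (adjusted Mazziotta-Pareto index) and ranking.

For one unit with normalized values r_1..r_k, let M be their (weighted)
arithmetic mean and S their (weighted, population-form) standard deviation,
with cv = S / M the coefficient of variation across the unit's own
indicators ("horizontal" variability).  The aggregate is

    score = M - S * cv   (minus direction; penalizes imbalance)
    score = M + S * cv   (plus direction)

i.e. ``M -/+ S**2 / M``.  The penalty makes the aggregation non-compensatory:
among units with the same mean, the one with more imbalance between
indicators scores strictly lower in the minus direction.  On the 70-130
normalized scale both the pillar scores and the composite provably stay in
[70, 130] in min-max mode (Bhatia-Davis bound on the variance).

Pillars aggregate their member indicators; the composite aggregates either
the pillar scores (default) or all elementary indicators directly.
Ranks are descending in the composite, ties broken by panel order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import IndexConfig
from .errors import ConfigError
from .impute import HotDeckImputer
from .normalize import GoalpostNormalizer, NormalizedPanel


@dataclass(frozen=True)
class AmpiComponents:
    """Mean, penalty components and penalized score for one unit."""

    M: float
    S: float
    cv: float
    score: float


def _weighted_moments(
    values: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean and population SD along the last axis."""
    w = weights / weights.sum()
    # compute relative to the first value so constant inputs give S = 0 exactly
    d = values - values[..., :1]
    dmean = d @ w
    M = values[..., 0] + dmean
    var = ((d - dmean[..., None]) ** 2) @ w
    return M, np.sqrt(var)


def ampi(
    values: Sequence[float],
    direction: str = "minus",
    weights: Sequence[float] | None = None,
) -> AmpiComponents:
    """Penalized mean of one unit's normalized values.

    ``direction="minus"`` subtracts the penalty S*cv (S**2/M), ``"plus"``
    adds it.  Equal weights reduce to the unweighted formulas.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("ampi requires a non-empty 1-d value list")
    if direction not in ("minus", "plus"):
        raise ValueError(f"unknown direction {direction!r}")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != v.shape:
        raise ValueError("weights must match values")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    M, S = _weighted_moments(v[None, :], w)
    M, S = float(M[0]), float(S[0])
    if M == 0:
        raise ZeroDivisionError("coefficient of variation undefined at mean 0")
    cv = S / M
    penalty = S * cv
    score = M - penalty if direction == "minus" else M + penalty
    return AmpiComponents(M=M, S=S, cv=cv, score=score)


def _ampi_frame(
    values: pd.DataFrame, direction: str, weights: np.ndarray
) -> pd.Series:
    """Vectorized penalized mean across the columns of a DataFrame."""
    M, S = _weighted_moments(values.to_numpy(dtype=float), weights)
    if np.any(M == 0):
        raise ZeroDivisionError("coefficient of variation undefined at mean 0")
    penalty = S * S / M
    score = M - penalty if direction == "minus" else M + penalty
    return pd.Series(score, index=values.index)


class AmpiAggregator(BaseEstimator, TransformerMixin):
    """Transformer mapping normalized indicators to pillar scores.

    Parameters
    ----------
    pillars : mapping pillar name -> list of indicator columns.
    direction : {"minus", "plus"}
    weights : mapping indicator -> positive weight (default all 1).
    """

    def __init__(
        self,
        pillars: Mapping[str, Sequence[str]],
        direction: str = "minus",
        weights: Mapping[str, float] | None = None,
    ):
        self.pillars = pillars
        self.direction = direction
        self.weights = weights

    def fit(self, X: pd.DataFrame, y=None) -> "AmpiAggregator":
        for pillar, cols in self.pillars.items():
            if len(cols) == 0:
                raise ConfigError(f"pillar {pillar!r} has no indicators")
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise ConfigError(
                    f"pillar {pillar!r}: columns not in panel: {missing}"
                )
        self.pillar_names_ = list(self.pillars)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "pillar_names_"):
            raise ValueError("AmpiAggregator is not fitted")
        wmap = dict(self.weights or {})
        out = pd.DataFrame(index=X.index, columns=self.pillar_names_, dtype=float)
        for pillar, cols in self.pillars.items():
            cols = list(cols)
            w = np.array([wmap.get(c, 1.0) for c in cols], dtype=float)
            if len(cols) == 1:
                out[pillar] = X[cols[0]]  # single-indicator pillar passes through
            else:
                out[pillar] = _ampi_frame(X[cols], self.direction, w)
        return out


@dataclass
class CompositeResult:
    """Per-unit pillar scores, composite value and rank (1 = best)."""

    pillar_scores: pd.DataFrame
    cih: pd.Series
    rank: pd.Series

    @property
    def unit_ids(self) -> list[str]:
        return [str(u) for u in self.cih.index]

    def to_frame(self) -> pd.DataFrame:
        frame = self.pillar_scores.copy()
        frame["cih"] = self.cih
        frame["rank"] = self.rank
        frame.index.name = "unit"
        return frame


def rank_descending(values: pd.Series) -> pd.Series:
    """Ranks 1..n, highest value first; ties keep panel (index) order."""
    order = np.lexsort((np.arange(len(values)), -values.to_numpy()))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return pd.Series(ranks, index=values.index)


def compute_pillars(norm: NormalizedPanel, config: IndexConfig) -> pd.DataFrame:
    """Aggregate a normalized panel into per-pillar penalized-mean scores."""
    agg = AmpiAggregator(
        pillars=config.pillars,
        direction=config.ampi_direction,
        weights=config.weights,
    )
    return agg.fit(norm.values).transform(norm.values)


def compute_composite(
    pillars: pd.DataFrame,
    config: IndexConfig,
    norm: NormalizedPanel | None = None,
) -> CompositeResult:
    """Aggregate pillar scores (or all indicators) into the composite index.

    With ``composite_level="indicators"`` the composite is the penalized mean
    of all normalized indicator values directly, in which case ``norm`` is
    required; pillar scores are still reported alongside.
    """
    if config.composite_level == "indicators":
        if norm is None:
            raise ValueError("composite_level='indicators' requires the normalized panel")
        w = np.array(
            [config.weights[c] for c in norm.values.columns], dtype=float
        )
        cih = _ampi_frame(norm.values, config.ampi_direction, w)
    elif pillars.shape[1] == 1:
        cih = pillars.iloc[:, 0].copy()
    else:
        w = np.ones(pillars.shape[1])
        cih = _ampi_frame(pillars, config.ampi_direction, w)
    cih.name = "cih"
    return CompositeResult(
        pillar_scores=pillars, cih=cih, rank=rank_descending(cih)
    )


class CompositeIndex(BaseEstimator):
    """End-to-end composite-index estimator: impute, normalize, aggregate, rank.

    ``fit(panel)`` runs the full construction on a units x indicators
    DataFrame and exposes the results as fitted attributes; ``transform``
    scores further panels against the goalposts and donor pool learned in
    ``fit`` (for the usual single-panel workflow use ``fit`` and read the
    attributes, or the :func:`build_composite` convenience function).

    Parameters
    ----------
    config : IndexConfig
        Indicator, pillar, polarity and option declaration.
    impute : bool, default True
        Hot-deck impute missing cells before normalizing.

    Attributes
    ----------
    imputation_report_ : DataFrame of filled cells (empty if none).
    normalized_ : NormalizedPanel (values, goalposts, out-of-range cells).
    pillar_scores_ : DataFrame, units x pillars.
    cih_ : Series of composite values; rank_ : Series of ranks (1 = best).
    result_ : CompositeResult bundling the above.
    """

    def __init__(self, config: IndexConfig, impute: bool = True):
        self.config = config
        self.impute = impute

    def fit(self, X: pd.DataFrame, y=None) -> "CompositeIndex":
        from .io import validate_panel

        config = self.config
        panel = validate_panel(X, config)
        self.imputer_ = HotDeckImputer(reference_values=config.reference_values)
        if self.impute:
            panel = self.imputer_.fit(panel).transform(panel)
            self.imputation_report_ = self.imputer_.report_
        else:
            if panel.isna().any().any():
                raise ValueError("panel has missing cells and impute=False")
            self.imputer_.fit(panel)
            self.imputation_report_ = pd.DataFrame(
                columns=["unit", "indicator", "value", "method", "donor_unit"]
            )
        self.scaler_ = GoalpostNormalizer(
            polarities=config.polarities,
            mode=config.normalization_mode,
            reference_values=config.reference_values,
        )
        values = self.scaler_.fit(panel).transform(panel)
        self.normalized_ = NormalizedPanel(
            values=values,
            goalposts=self.scaler_.goalposts_,
            out_of_range=self.scaler_.out_of_range_,
        )
        self.aggregator_ = AmpiAggregator(
            pillars=config.pillars,
            direction=config.ampi_direction,
            weights=config.weights,
        )
        self.pillar_scores_ = self.aggregator_.fit(values).transform(values)
        self.result_ = compute_composite(
            self.pillar_scores_, config, norm=self.normalized_
        )
        self.cih_ = self.result_.cih
        self.rank_ = self.result_.rank
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score a panel with the fitted goalposts; returns pillars + cih."""
        if not hasattr(self, "scaler_"):
            raise ValueError("CompositeIndex is not fitted")
        from .io import validate_panel

        panel = validate_panel(X, self.config)
        if self.impute:
            panel = self.imputer_.transform(panel)
        values = self.scaler_.transform(panel)
        pillars = self.aggregator_.transform(values)
        norm = NormalizedPanel(values=values, goalposts=self.scaler_.goalposts_,
                               out_of_range=self.scaler_.out_of_range_)
        result = compute_composite(pillars, self.config, norm=norm)
        return result.to_frame()

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        self.fit(X)
        return self.result_.to_frame()


def build_composite(panel: pd.DataFrame, config: IndexConfig) -> CompositeResult:
    """One-shot pipeline: impute, normalize, aggregate, rank."""
    return CompositeIndex(config).fit(panel).result_
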