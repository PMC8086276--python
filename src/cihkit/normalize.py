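"""Goalpost normalization of raw indicators onto the common 70-130 scale.

Each indicator gets a pair of *goalposts* ``(low, high)`` anchoring an
affine map onto [70, 130]:

* ``minmax`` mode: goalposts are the observed column minimum and maximum,
  so every normalized value lies in [70, 130] by construction;
* ``reference`` mode: goalposts are ``ref - delta`` and ``ref + delta`` with
  ``delta = (max - min) / 2``, so a unit sitting exactly at the reference
  value maps to 100 regardless of polarity.  Values may then fall outside
  [70, 130]; they are reported, never clamped, because clamping would break
  the affine invariance the penalty method relies on.

Positive polarity: ``r = 60 * (x - low) / (high - low) + 70``.
Negative polarity reflects the scale: ``r = 60 * (high - x) / (high - low) + 70``,
so for the same column positive and negative normalizations sum to 200.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import IndexConfig
from .errors import DegenerateIndicatorError

SCALE_LOW = 70.0
SCALE_HIGH = 130.0
SCALE_SPAN = SCALE_HIGH - SCALE_LOW  # the 60-point width of the index scale


@dataclass
class NormalizedPanel:
    """A complete normalized panel plus the goalposts that produced it."""

    values: pd.DataFrame
    goalposts: dict[str, tuple[float, float]]
    out_of_range: list[tuple[str, str, float]]

    @property
    def unit_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def indicator_names(self) -> list[str]:
        return list(self.values.columns)


class GoalpostNormalizer(BaseEstimator, TransformerMixin):
    """Affine goalpost scaler with polarity reflection.

    Parameters
    ----------
    polarities : mapping indicator -> {"positive", "negative"}
        Columns absent from the mapping default to positive.
    mode : {"minmax", "reference"}
        Goalpost rule (observed range, or reference +/- half-range).
    reference_values : mapping indicator -> float
        Required in reference mode.

    Attributes
    ----------
    goalposts_ : dict indicator -> (low, high), learned in ``fit``.
    out_of_range_ : list of (unit, indicator, normalized value) cells outside
        [70, 130] in the last ``transform`` (reference mode only).
    """

    def __init__(
        self,
        polarities: Mapping[str, str] | None = None,
        mode: str = "minmax",
        reference_values: Mapping[str, float] | None = None,
    ):
        self.polarities = polarities
        self.mode = mode
        self.reference_values = reference_values

    def fit(self, X: pd.DataFrame, y=None) -> "GoalpostNormalizer":
        if self.mode not in ("minmax", "reference"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        X = X.astype(float)
        if X.isna().any().any():
            raise ValueError("normalization requires a complete panel (impute first)")
        refs = dict(self.reference_values or {})
        goalposts: dict[str, tuple[float, float]] = {}
        for col in X.columns:
            lo, hi = float(X[col].min()), float(X[col].max())
            if hi <= lo:
                raise DegenerateIndicatorError(
                    f"indicator {col!r} is constant; goalposts collapse"
                )
            if self.mode == "reference":
                if col not in refs:
                    raise ValueError(
                        f"reference mode requires a reference value for {col!r}"
                    )
                delta = (hi - lo) / 2.0
                ref = float(refs[col])
                goalposts[col] = (ref - delta, ref + delta)
            else:
                goalposts[col] = (lo, hi)
        self.goalposts_ = goalposts
        self.feature_names_in_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "goalposts_"):
            raise ValueError("GoalpostNormalizer is not fitted")
        X = X.astype(float)
        polarities = dict(self.polarities or {})
        out = pd.DataFrame(index=X.index, columns=X.columns, dtype=float)
        out_of_range: list[tuple[str, str, float]] = []
        for col in X.columns:
            low, high = self.goalposts_[col]
            span = high - low
            if polarities.get(col, "positive") == "negative":
                r = SCALE_SPAN * (high - X[col]) / span + SCALE_LOW
            else:
                r = SCALE_SPAN * (X[col] - low) / span + SCALE_LOW
            out[col] = r
            bad = r[(r < SCALE_LOW - 1e-12) | (r > SCALE_HIGH + 1e-12)]
            for unit, value in bad.items():
                out_of_range.append((str(unit), str(col), float(value)))
        self.out_of_range_ = out_of_range
        return out


def normalize(panel: pd.DataFrame, config: IndexConfig) -> NormalizedPanel:
    """Normalize a complete panel under a configuration."""
    scaler = GoalpostNormalizer(
        polarities=config.polarities,
        mode=config.normalization_mode,
        reference_values=config.reference_values,
    )
    values = scaler.fit(panel).transform(panel)
    return NormalizedPanel(
        values=values,
        goalposts=scaler.goalposts_,
        out_of_range=scaler.out_of_range_,
    )
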