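"""Leave-one-indicator-out influence analysis of the composite ranking.

For each elementary indicator k the whole construction (imputation,
normalization with freshly recomputed goalposts, pillar and composite
aggregation, ranking) is rerun on the configuration without k, and the
per-unit rank shift ``rank(full) - rank(without k)`` is summarized by

* ``sigma``  — the root-mean-square shift (equal to the population SD of the
  shifts, since both rankings are permutations of 1..n and the mean shift
  is exactly zero);
* ``mean_abs_shift`` and ``max_shift`` — companion magnitudes.

Indicators whose removal reshuffles the ranking strongly are the ones the
index leans on.  When k is its pillar's only indicator, that pillar drops
out of the composite for the rerun (logged).
"""

from __future__ import annotations

import logging

import pandas as pd

from .aggregate import build_composite
from .config import IndexConfig
from .errors import ConfigError

logger = logging.getLogger(__name__)


def influence_analysis(
    panel: pd.DataFrame,
    config: IndexConfig,
    use_scores: bool = False,
) -> pd.DataFrame:
    """Influence of each indicator's removal on the composite ranking.

    Returns a DataFrame indexed by indicator with columns ``pillar``,
    ``sigma``, ``mean_abs_shift``, ``max_shift``, sorted by sigma
    descending.  With ``use_scores=True`` shifts are differences of
    composite values instead of ranks (non-default variant).
    """
    if len(config.indicators) < 2:
        raise ConfigError("influence analysis needs at least two indicators")
    full = build_composite(panel, config)
    baseline = full.cih if use_scores else full.rank.astype(float)

    rows = []
    for spec in config.indicators:
        reduced_cfg = config.drop_indicator(spec.name)
        if spec.pillar not in reduced_cfg.pillars:
            logger.info(
                "indicator %r is the only member of pillar %r; "
                "the pillar is dropped for this rerun", spec.name, spec.pillar,
            )
        reduced = build_composite(panel.drop(columns=[spec.name]), reduced_cfg)
        other = reduced.cih if use_scores else reduced.rank.astype(float)
        shift = (baseline - other).astype(float)
        rows.append(
            {
                "indicator": spec.name,
                "pillar": spec.pillar,
                "sigma": float((shift**2).mean() ** 0.5),
                "mean_abs_shift": float(shift.abs().mean()),
                "max_shift": float(shift.abs().max()),
            }
        )
    table = pd.DataFrame(rows).set_index("indicator")
    return table.sort_values("sigma", ascending=False, kind="stable")
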