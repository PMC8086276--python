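"""Synthetic indicator panels with known pillar structure, polarity mix,
spatial autocorrelation and missingness.

Units sit on a rook-contiguity lattice.  A latent "health" factor follows a
simultaneous-autoregressive (SAR) scheme, u = (I - rho*W)^-1 eps with W the
row-standardized contiguity matrix and eps i.i.d. standard normal, so rho
in (-1, 1) controls the spatial autocorrelation of everything downstream.
Each pillar factor mixes the shared latent factor with idiosyncratic noise
(p = a*u + b*eta, a = pillar_loading, b = sqrt(1 - a^2)), and each indicator
is an affine read-out of its pillar factor plus observation noise, sign-
flipped before the offset for negative-polarity indicators so that healthier
units show *lower* raw values there (mortality-rate style).  Cells are
finally dropped missing-completely-at-random.

The default layout mirrors the 23-indicator / 6-pillar well-being schema
(environment 8 indicators with 3 negative, social distress 4/4 negative,
culture 4/0, health 5/4 negative, work 1, material well-being 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import IndexConfig, IndicatorSpec
from .spatial import SpatialWeights, lattice_weights

#: (pillar, number of indicators, fraction with negative polarity)
DEFAULT_PILLAR_SPEC: tuple[tuple[str, int, float], ...] = (
    ("environment", 8, 0.375),
    ("social_distress", 4, 1.0),
    ("culture", 4, 0.0),
    ("health", 5, 0.8),
    ("work", 1, 0.0),
    ("material_wellbeing", 1, 0.0),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic panel generator.

    rows, cols: lattice dimensions (n = rows * cols units).
    pillar_spec: per-pillar (name, indicator count, negative fraction).
    rho: SAR spatial-autocorrelation parameter, |rho| < 1.
    loading: indicator loading on its pillar factor.
    pillar_loading: weight of the shared latent factor within each pillar
        factor (idiosyncratic share is sqrt(1 - pillar_loading**2)).
    noise_sd: SD of indicator-level observation noise.
    missing_rate: MCAR cell-missingness probability.
    seed: generator seed (all draws flow from it).
    """

    rows: int = 8
    cols: int = 8
    pillar_spec: tuple[tuple[str, int, float], ...] = DEFAULT_PILLAR_SPEC
    rho: float = 0.4
    loading: float = 1.0
    pillar_loading: float = 0.85
    noise_sd: float = 0.5
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.pillar_loading <= 1:
            raise ValueError("pillar_loading must be in (0, 1]")


@dataclass
class SimOutput:
    """Generated panel plus its configuration, weights and ground truth."""

    panel: pd.DataFrame
    config: IndexConfig
    weights: SpatialWeights
    truth: pd.DataFrame = field(repr=False)


def _build_config(pillar_spec) -> IndexConfig:
    indicators = []
    for pillar, n_ind, frac_neg in pillar_spec:
        n_neg = int(round(frac_neg * n_ind))
        for i in range(n_ind):
            indicators.append(
                IndicatorSpec(
                    name=f"{pillar}_{i + 1}",
                    pillar=pillar,
                    polarity="negative" if i < n_neg else "positive",
                )
            )
    return IndexConfig(indicators=tuple(indicators))


def simulate_panel(sim: SimConfig) -> SimOutput:
    """Generate one panel under a :class:`SimConfig` (deterministic in seed)."""
    rng = np.random.default_rng(sim.seed)
    weights = lattice_weights(sim.rows, sim.cols, scheme="rook")
    ids = weights.unit_ids
    n = weights.n
    W = weights.to_dense()

    eps = rng.standard_normal(n)
    u = np.linalg.solve(np.eye(n) - sim.rho * W, eps)

    config = _build_config(sim.pillar_spec)
    a = sim.pillar_loading
    b = float(np.sqrt(1.0 - a * a))
    pillar_factors: dict[str, np.ndarray] = {}
    for pillar, _, _ in sim.pillar_spec:
        pillar_factors[pillar] = a * u + b * rng.standard_normal(n)

    columns = {}
    for spec in config.indicators:
        signal = sim.loading * pillar_factors[spec.pillar]
        signal = signal + sim.noise_sd * rng.standard_normal(n)
        if spec.polarity == "negative":
            signal = -signal
        columns[spec.name] = 100.0 + signal
    panel = pd.DataFrame(columns, index=pd.Index(ids, name="unit"))

    if sim.missing_rate > 0:
        mask = rng.random(panel.shape) < sim.missing_rate
        panel = panel.mask(mask)

    truth = pd.DataFrame(
        {"latent_health": u, **{f"factor_{p}": f for p, f in pillar_factors.items()}},
        index=pd.Index(ids, name="unit"),
    )
    return SimOutput(panel=panel, config=config, weights=weights, truth=truth)
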