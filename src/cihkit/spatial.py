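"""Spatial autocorrelation: contiguity weights, global Moran's I, local
Moran (LISA) with permutation inference, and cluster classification.

Weights are binary contiguity relations (symmetric before standardization)
read from a GeoDa-style GAL file, an edge-list CSV, or built on a regular
lattice; rows are standardized to sum to one.  With standardized values
``z_i = (x_i - mean) / SD`` (population SD),

    global:  I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i**2
    local:   I_i = (z_i / m2) * sum_j w_ij z_j,   m2 = sum_k z_k**2 / n

so with row-standardized weights the mean of the local statistics over
non-island units equals the global I.  The expectation of I under the null
of no spatial structure is -1/(n-1).

Inference is by permutation: the global test permutes all values over the
units; the local (conditional) test holds z_i fixed and permutes the
remaining n-1 values over i's neighbor positions.  Pseudo p-values are
two-sided with the +1 correction, referenced to -1/(n-1) (global) and 0
(local).  Significant units are classified by the signs of (z_i, lag_i)
into High-High, Low-Low, Low-High and High-Low clusters; the rest are
Not-significant.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import WeightsFormatError, ZeroVarianceError
from .io import LISA_COLORS

logger = logging.getLogger(__name__)

QUADRANTS = ("HH", "LL", "LH", "HL")


@dataclass
class SpatialWeights:
    """Row-standardized contiguity weights over named units."""

    unit_ids: list[str]
    neighbors: Mapping[str, list[str]]
    islands: list[str] = field(init=False)

    def __post_init__(self) -> None:
        ids = set(self.unit_ids)
        if len(ids) != len(self.unit_ids):
            raise WeightsFormatError("duplicate unit ids in weights")
        for uid, nbrs in self.neighbors.items():
            if uid not in ids:
                raise WeightsFormatError(f"neighbor list for unknown unit {uid!r}")
            for v in nbrs:
                if v not in ids:
                    raise WeightsFormatError(
                        f"unit {uid!r} lists undeclared neighbor {v!r}"
                    )
                if v == uid:
                    raise WeightsFormatError(f"unit {uid!r} is its own neighbor")
        # symmetrize (union) if needed
        asym = [
            (u, v)
            for u, nbrs in self.neighbors.items()
            for v in nbrs
            if u not in self.neighbors.get(v, [])
        ]
        if asym:
            warnings.warn(
                f"adjacency not symmetric; symmetrizing by union ({len(asym)} "
                "missing reciprocal link(s))",
                stacklevel=2,
            )
            fixed = {u: list(nbrs) for u, nbrs in self.neighbors.items()}
            for u, v in asym:
                fixed.setdefault(v, []).append(u)
            object.__setattr__(self, "neighbors", fixed)
        self.islands = [u for u in self.unit_ids if not self.neighbors.get(u)]

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def neighbor_counts(self) -> dict[str, int]:
        return {u: len(self.neighbors.get(u, [])) for u in self.unit_ids}

    def n_edges(self) -> int:
        return sum(len(self.neighbors.get(u, [])) for u in self.unit_ids) // 2

    def to_dense(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """Row-standardized weight matrix aligned to ``ids`` (default all)."""
        ids = list(ids) if ids is not None else list(self.unit_ids)
        pos = {u: i for i, u in enumerate(ids)}
        W = np.zeros((len(ids), len(ids)))
        for u in ids:
            nbrs = [v for v in self.neighbors.get(u, []) if v in pos]
            if not nbrs:
                continue
            w = 1.0 / len(nbrs)
            for v in nbrs:
                W[pos[u], pos[v]] = w
        return W

    def subset(self, ids: Sequence[str]) -> "SpatialWeights":
        keep = set(ids)
        return SpatialWeights(
            unit_ids=[u for u in self.unit_ids if u in keep],
            neighbors={
                u: [v for v in self.neighbors.get(u, []) if v in keep]
                for u in self.unit_ids
                if u in keep
            },
        )


def read_gal(path: str | Path) -> SpatialWeights:
    """Read a GAL contiguity file (GeoDa dialect).

    Header is either ``0 n <name> <key>`` or a bare ``n``; each unit then
    occupies two lines: ``id k`` and a line with its k neighbor ids.
    Asymmetric adjacency is symmetrized by union with a warning.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text("utf-8").splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise WeightsFormatError(f"{path}: empty GAL file")
    header = lines[0].split()
    try:
        n_declared = int(header[1]) if len(header) > 1 else int(header[0])
    except ValueError:
        raise WeightsFormatError(f"{path}: malformed header {lines[0]!r}") from None

    unit_ids: list[str] = []
    neighbors: dict[str, list[str]] = {}
    i = 1
    while i < len(lines):
        head = lines[i].split()
        if len(head) != 2:
            raise WeightsFormatError(
                f"{path}: expected 'id k' line, got {lines[i]!r}"
            )
        uid, k_str = head
        try:
            k = int(k_str)
        except ValueError:
            raise WeightsFormatError(
                f"{path}: non-integer neighbor count in {lines[i]!r}"
            ) from None
        if uid in neighbors:
            raise WeightsFormatError(f"{path}: duplicate unit {uid!r}")
        if k == 0:
            nbrs: list[str] = []
            i += 1
        else:
            if i + 1 >= len(lines):
                raise WeightsFormatError(f"{path}: missing neighbor line for {uid!r}")
            nbrs = lines[i + 1].split()
            if len(nbrs) != k:
                raise WeightsFormatError(
                    f"{path}: unit {uid!r} declares {k} neighbors but lists "
                    f"{len(nbrs)}"
                )
            i += 2
        unit_ids.append(uid)
        neighbors[uid] = nbrs
    if len(unit_ids) != n_declared:
        raise WeightsFormatError(
            f"{path}: header declares {n_declared} units, found {len(unit_ids)}"
        )
    for uid, nbrs in neighbors.items():
        for v in nbrs:
            if v not in neighbors:
                raise WeightsFormatError(
                    f"{path}: unit {uid!r} lists undeclared neighbor {v!r}"
                )
    return SpatialWeights(unit_ids=unit_ids, neighbors=neighbors)


def write_gal(weights: SpatialWeights, path: str | Path) -> None:
    lines = [str(weights.n)]
    for u in weights.unit_ids:
        nbrs = weights.neighbors.get(u, [])
        lines.append(f"{u} {len(nbrs)}")
        if nbrs:
            lines.append(" ".join(nbrs))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_edge_list(path: str | Path) -> SpatialWeights:
    """Read contiguity from a CSV with columns ``unit_a, unit_b``."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"unit_a", "unit_b"} <= set(
            reader.fieldnames
        ):
            raise WeightsFormatError(f"{path}: expected columns unit_a, unit_b")
        pairs = [(row["unit_a"].strip(), row["unit_b"].strip()) for row in reader]
    unit_ids: list[str] = []
    neighbors: dict[str, list[str]] = {}
    for a, b in pairs:
        for u in (a, b):
            if u not in neighbors:
                neighbors[u] = []
                unit_ids.append(u)
        if b not in neighbors[a]:
            neighbors[a].append(b)
        if a not in neighbors[b]:
            neighbors[b].append(a)
    return SpatialWeights(unit_ids=unit_ids, neighbors=neighbors)


def lattice_weights(rows: int, cols: int, scheme: str = "rook") -> SpatialWeights:
    """Contiguity weights on a rows x cols grid (rook or queen scheme).

    Units are named ``u1..u{rows*cols}`` in row-major order.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if scheme not in ("rook", "queen"):
        raise ValueError(f"unknown scheme {scheme!r}")
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]

    def name(r: int, c: int) -> str:
        return f"u{r * cols + c + 1}"

    unit_ids = [name(r, c) for r in range(rows) for c in range(cols)]
    neighbors = {
        name(r, c): [
            name(r + dr, c + dc)
            for dr, dc in steps
            if 0 <= r + dr < rows and 0 <= c + dc < cols
        ]
        for r in range(rows)
        for c in range(cols)
    }
    return SpatialWeights(unit_ids=unit_ids, neighbors=neighbors)


@dataclass
class MoranResult:
    """Global Moran's I with permutation pseudo p-value."""

    I: float
    expected: float
    z_values: pd.Series
    n_permutations: int
    pseudo_p: float | None
    seed: int | None


def _prepare(values: pd.Series, W: SpatialWeights, allow_islands: bool):
    values = values.astype(float)
    missing = [u for u in W.unit_ids if u not in values.index]
    if missing:
        raise ValueError(f"values missing for unit(s): {missing[:5]}")
    islands = list(W.islands)
    if islands and not allow_islands:
        raise ValueError(
            f"{len(islands)} island unit(s) (no neighbors): {islands[:5]}; "
            "pass allow_islands=True to exclude them"
        )
    ids = [u for u in W.unit_ids if u not in set(islands)]
    if len(ids) < 3:
        raise ValueError("need at least 3 non-island units")
    x = values.loc[ids].to_numpy()
    sd = x.std()  # population SD
    if sd == 0:
        raise ZeroVarianceError("values are constant; Moran's I undefined")
    z = (x - x.mean()) / sd
    Wm = W.to_dense(ids)
    return ids, z, Wm, islands


def global_moran(
    values: pd.Series,
    W: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    allow_islands: bool = False,
) -> MoranResult:
    """Global Moran's I with a total-permutation pseudo p-value.

    The two-sided pseudo p counts permuted statistics at least as far from
    the null expectation -1/(n-1) as the observed one, with the +1
    correction.  ``n_permutations=0`` skips inference (pseudo_p None).
    """
    ids, z, Wm, _ = _prepare(values, W, allow_islands)
    n = len(ids)
    S0 = Wm.sum()
    denom = float(z @ z)
    I_obs = float((n / S0) * (z @ (Wm @ z)) / denom)
    expected = -1.0 / (n - 1)

    pseudo_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        ref = abs(I_obs - expected)
        for _ in range(n_permutations):
            zp = rng.permutation(z)
            I_perm = float((n / S0) * (zp @ (Wm @ zp)) / denom)
            if abs(I_perm - expected) >= ref - 1e-14:
                count += 1
        pseudo_p = (1 + count) / (n_permutations + 1)
    return MoranResult(
        I=I_obs,
        expected=expected,
        z_values=pd.Series(z, index=ids),
        n_permutations=n_permutations,
        pseudo_p=pseudo_p,
        seed=seed,
    )


def _quadrant(zi: float, lag: float) -> str:
    hi_i = zi > 0
    hi_lag = lag > 0
    if hi_i:
        return "HH" if hi_lag else "HL"
    return "LH" if hi_lag else "LL"


def local_moran(
    values: pd.Series,
    W: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    allow_islands: bool = False,
) -> pd.DataFrame:
    """Local Moran (LISA) table with conditional permutation inference.

    Returns a DataFrame indexed by unit with columns ``local_I``, ``lag``,
    ``pseudo_p``, ``quadrant``, ``label`` and ``island``.  For each unit the
    conditional test fixes z_i and redraws its neighbors' values from the
    remaining n-1, two-sided against 0 with the +1 correction; ``label``
    equals the quadrant when pseudo_p < alpha, else ``"NS"``.  Islands (only
    with ``allow_islands=True``) are labeled NS and flagged.
    """
    ids, z, Wm, islands = _prepare(values, W, allow_islands)
    n = len(ids)
    m2 = float(z @ z) / n
    lag = Wm @ z
    local_I = z * lag / m2

    rng = np.random.default_rng(seed)
    pseudo_p = np.full(n, np.nan)
    pos = {u: i for i, u in enumerate(ids)}
    for i, uid in enumerate(ids):
        nbrs = [v for v in W.neighbors.get(uid, []) if v in pos]
        k = len(nbrs)
        others = np.delete(z, i)
        w_row = np.full(k, 1.0 / k)
        # each row of keys induces a uniform random k-subset in random order
        keys = rng.random((n_permutations, n - 1))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < n - 1 else (
            np.argsort(keys, axis=1)
        )
        lag_perm = others[idx] @ w_row
        I_perm = z[i] * lag_perm / m2
        count = int(np.sum(np.abs(I_perm) >= abs(local_I[i]) - 1e-14))
        pseudo_p[i] = (1 + count) / (n_permutations + 1)

    quadrant = [_quadrant(z[i], lag[i]) for i in range(n)]
    label = [
        q if p < alpha else "NS" for q, p in zip(quadrant, pseudo_p)
    ]
    table = pd.DataFrame(
        {
            "local_I": local_I,
            "lag": lag,
            "pseudo_p": pseudo_p,
            "quadrant": quadrant,
            "label": label,
            "island": False,
        },
        index=pd.Index(ids, name="unit"),
    )
    if islands:
        island_rows = pd.DataFrame(
            {
                "local_I": np.nan,
                "lag": np.nan,
                "pseudo_p": np.nan,
                "quadrant": "NS",
                "label": "NS",
                "island": True,
            },
            index=pd.Index(islands, name="unit"),
        )
        table = pd.concat([table, island_rows]).loc[list(W.unit_ids)]
        table.index.name = "unit"
    return table


def classify_clusters(lisa: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Five-category cluster classification with GeoDa color tags.

    Relabels a LISA table at significance level ``alpha`` and appends the
    conventional colors: Not-significant white, High-High red, Low-Low
    blue, Low-High light blue, High-Low light red.
    """
    out = lisa.copy()
    labels = []
    for _, row in out.iterrows():
        if row.get("island", False) or not (row["pseudo_p"] < alpha):
            labels.append("NS")
        else:
            labels.append(row["quadrant"])
    out["label"] = labels
    out["color"] = [LISA_COLORS[lab] for lab in labels]
    return out
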