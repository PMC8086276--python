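"""Reading and writing external formats: indicator panels, score tables,
GeoJSON cluster-map exports.

Panels are CSV, UTF-8, one header row, with the unit identifier in a column
named ``unit`` and one column per configured indicator.  Empty cells and the
token ``NA`` both denote missing values.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .config import IndexConfig
from .errors import GeoJoinError, PanelParseError, PanelSchemaError

if TYPE_CHECKING:  # pragma: no cover
    from .aggregate import CompositeResult

logger = logging.getLogger(__name__)

UNIT_COLUMN = "unit"
MISSING_TOKENS = ("", "NA")

#: GeoDa-convention colors for the five LISA cluster categories.
LISA_COLORS = {
    "NS": "white",
    "HH": "red",
    "LL": "blue",
    "LH": "light blue",
    "HL": "light red",
}


def read_panel(path: str | Path, config: IndexConfig) -> pd.DataFrame:
    """Read a units x indicators panel CSV against a configuration.

    Returns a DataFrame indexed by unit id with one float column per
    configured indicator (in configuration order); missing cells are NaN.
    Extra columns are ignored with a warning; a missing configured column,
    a duplicate unit id, or a non-numeric cell is an error.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PanelSchemaError(f"{path}: empty file") from None
        rows = list(reader)

    if UNIT_COLUMN not in header:
        raise PanelSchemaError(f"{path}: missing unit-id column {UNIT_COLUMN!r}")
    missing_cols = [n for n in config.indicator_names if n not in header]
    if missing_cols:
        raise PanelSchemaError(
            f"{path}: missing configured indicator column(s): "
            + ", ".join(missing_cols)
        )
    extra = [c for c in header if c != UNIT_COLUMN and c not in config.indicator_names]
    if extra:
        logger.warning("%s: ignoring extra column(s): %s", path, ", ".join(extra))

    col_idx = {name: header.index(name) for name in config.indicator_names}
    unit_idx = header.index(UNIT_COLUMN)

    unit_ids: list[str] = []
    data: list[list[float]] = []
    for r, row in enumerate(rows, start=2):  # 1-based, header is line 1
        if not row or all(cell.strip() == "" for cell in row):
            continue
        unit = row[unit_idx].strip()
        if unit in unit_ids:
            raise PanelSchemaError(f"{path}: duplicate unit id {unit!r}")
        unit_ids.append(unit)
        values = []
        for name in config.indicator_names:
            cell = row[col_idx[name]].strip()
            if cell in MISSING_TOKENS:
                values.append(np.nan)
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise PanelParseError(
                    f"{path}: non-numeric value {cell!r} at line {r}, "
                    f"column {name!r}"
                ) from None
        data.append(values)

    if len(unit_ids) < 2:
        raise PanelSchemaError(f"{path}: a panel needs at least 2 units")
    frame = pd.DataFrame(data, index=unit_ids, columns=config.indicator_names)
    frame.index.name = UNIT_COLUMN
    return frame


def validate_panel(panel: pd.DataFrame, config: IndexConfig) -> pd.DataFrame:
    """Check an in-memory panel against a config and order its columns."""
    missing = [n for n in config.indicator_names if n not in panel.columns]
    if missing:
        raise PanelSchemaError(
            "panel missing configured indicator column(s): " + ", ".join(missing)
        )
    if panel.index.has_duplicates:
        dupes = panel.index[panel.index.duplicated()].unique().tolist()
        raise PanelSchemaError(f"duplicate unit id(s): {dupes}")
    if len(panel) < 2:
        raise PanelSchemaError("a panel needs at least 2 units")
    return panel[config.indicator_names].astype(float)


def write_scores(result: "CompositeResult", path: str | Path) -> None:
    """Write per-unit pillar scores, composite value and rank as CSV."""
    frame = result.to_frame()
    frame.to_csv(path, index=True, float_format="%.6f")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a score table written by :func:`write_scores`."""
    return pd.read_csv(path, index_col=UNIT_COLUMN)


def export_geojson(
    result: "CompositeResult",
    lisa: pd.DataFrame | None,
    geojson_in: str | Path,
    path: str | Path,
    *,
    permissive: bool = False,
    id_property: str = UNIT_COLUMN,
) -> None:
    """Append composite and LISA attributes to a GeoJSON feature collection.

    Each feature must carry a ``unit`` property (configurable) matching a
    panel unit id; features gain properties ``cih``, ``rank`` and, when a
    LISA table is given, ``lisa_class`` and ``lisa_color``.  Panel units
    absent from the GeoJSON raise :class:`GeoJoinError` unless ``permissive``.
    """
    geojson_in = Path(geojson_in)
    doc = json.loads(geojson_in.read_text("utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise GeoJoinError(f"{geojson_in}: not a GeoJSON FeatureCollection")
    features = doc.get("features", [])
    feature_ids = set()
    for feat in features:
        props = feat.setdefault("properties", {})
        if id_property in props:
            feature_ids.add(str(props[id_property]))

    missing = [u for u in result.unit_ids if u not in feature_ids]
    if missing:
        msg = "unit(s) absent from GeoJSON: " + ", ".join(missing)
        if permissive:
            logger.warning(msg)
        else:
            raise GeoJoinError(msg)

    cih = result.cih
    rank = result.rank
    for feat in features:
        props = feat["properties"]
        uid = str(props.get(id_property, ""))
        if uid not in cih.index:
            continue
        props["cih"] = float(cih.loc[uid])
        props["rank"] = int(rank.loc[uid])
        if lisa is not None and uid in lisa.index:
            label = str(lisa.loc[uid, "label"])
            props["lisa_class"] = label
            props["lisa_color"] = LISA_COLORS[label]
    Path(path).write_text(json.dumps(doc), encoding="utf-8")
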