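"""Index configuration: indicators, pillars, polarities and options.

A composite index is declared by an ordered list of elementary indicators,
each assigned to a pillar (thematic macro area) and carrying a polarity:
positive indicators increase with the concept being measured (e.g. life
expectancy for health), negative ones decrease with it (e.g. mortality
rates) and are reflected during normalization.

Configurations are JSON documents with top-level keys ``indicators`` (a list
of ``{"name", "pillar", "polarity", "weight"?}`` objects) and optional
``options`` (``normalization_mode``, ``ampi_direction``, ``composite_level``,
``reference_values``).  The 23-indicator / 6-pillar equitable-and-sustainable
well-being layout ships as the built-in configuration ``"eswb2015"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import ConfigError

POLARITIES = ("positive", "negative")
NORMALIZATION_MODES = ("minmax", "reference")
AMPI_DIRECTIONS = ("minus", "plus")
COMPOSITE_LEVELS = ("pillars", "indicators")

_BUILTIN_CONFIGS = ("eswb2015",)


@dataclass(frozen=True)
class IndicatorSpec:
    """One elementary indicator: name, pillar membership, polarity, weight."""

    name: str
    pillar: str
    polarity: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("indicator name must be non-empty")
        if not self.pillar:
            raise ConfigError(f"indicator {self.name!r}: pillar must be non-empty")
        if self.polarity not in POLARITIES:
            raise ConfigError(
                f"indicator {self.name!r}: unknown polarity {self.polarity!r} "
                f"(expected one of {POLARITIES})"
            )
        if not self.weight > 0:
            raise ConfigError(f"indicator {self.name!r}: weight must be > 0")


@dataclass(frozen=True)
class IndexConfig:
    """Full index declaration: ordered indicators plus construction options."""

    indicators: tuple[IndicatorSpec, ...]
    normalization_mode: str = "minmax"
    ampi_direction: str = "minus"
    composite_level: str = "pillars"
    reference_values: Mapping[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.indicators:
            raise ConfigError("config must declare at least one indicator")
        names = [spec.name for spec in self.indicators]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ConfigError(f"duplicate indicator name(s): {', '.join(dupes)}")
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ConfigError(
                f"unknown normalization_mode {self.normalization_mode!r}"
            )
        if self.ampi_direction not in AMPI_DIRECTIONS:
            raise ConfigError(f"unknown ampi_direction {self.ampi_direction!r}")
        if self.composite_level not in COMPOSITE_LEVELS:
            raise ConfigError(f"unknown composite_level {self.composite_level!r}")
        if self.normalization_mode == "reference":
            refs = self.reference_values or {}
            missing = [n for n in names if n not in refs]
            if missing:
                raise ConfigError(
                    "reference normalization requires a reference value for every "
                    f"indicator; missing: {', '.join(missing)}"
                )

    @property
    def indicator_names(self) -> list[str]:
        return [spec.name for spec in self.indicators]

    @property
    def pillars(self) -> dict[str, list[str]]:
        """Pillar -> indicator names, in declaration order."""
        out: dict[str, list[str]] = {}
        for spec in self.indicators:
            out.setdefault(spec.pillar, []).append(spec.name)
        return out

    @property
    def polarities(self) -> dict[str, str]:
        return {spec.name: spec.polarity for spec in self.indicators}

    @property
    def weights(self) -> dict[str, float]:
        return {spec.name: spec.weight for spec in self.indicators}

    def drop_indicator(self, name: str) -> "IndexConfig":
        """Configuration with one indicator removed (for influence analysis).

        If the indicator was its pillar's only member, the pillar disappears
        with it.  Removing the last indicator overall is an error.
        """
        if name not in self.indicator_names:
            raise ConfigError(f"cannot drop unknown indicator {name!r}")
        remaining = tuple(s for s in self.indicators if s.name != name)
        if not remaining:
            raise ConfigError("cannot drop the only indicator in the config")
        refs = None
        if self.reference_values is not None:
            refs = {k: v for k, v in self.reference_values.items() if k != name}
        return replace(self, indicators=remaining, reference_values=refs)

    def with_references(self, reference_values: Mapping[str, float]) -> "IndexConfig":
        return replace(
            self,
            normalization_mode="reference",
            reference_values=dict(reference_values),
        )


def _parse_indicator(obj: dict, index: int) -> IndicatorSpec:
    if not isinstance(obj, dict):
        raise ConfigError(f"indicators[{index}] must be an object")
    allowed = {"name", "pillar", "polarity", "weight"}
    unknown = set(obj) - allowed
    if unknown:
        raise ConfigError(
            f"indicators[{index}]: unknown key(s) {sorted(unknown)}"
        )
    for key in ("name", "pillar", "polarity"):
        if key not in obj:
            raise ConfigError(f"indicators[{index}]: missing required key {key!r}")
    weight = obj.get("weight", 1.0)
    if not isinstance(weight, (int, float)) or isinstance(weight, bool):
        raise ConfigError(f"indicators[{index}]: weight must be a number")
    return IndicatorSpec(
        name=str(obj["name"]),
        pillar=str(obj["pillar"]),
        polarity=str(obj["polarity"]),
        weight=float(weight),
    )


def _config_from_document(doc: dict, source: str) -> IndexConfig:
    if not isinstance(doc, dict):
        raise ConfigError(f"{source}: config document must be a JSON object")
    unknown = set(doc) - {"indicators", "options"}
    if unknown:
        raise ConfigError(f"{source}: unknown top-level key(s) {sorted(unknown)}")
    if "indicators" not in doc or not isinstance(doc["indicators"], list):
        raise ConfigError(f"{source}: missing or non-list 'indicators'")
    indicators = tuple(
        _parse_indicator(obj, i) for i, obj in enumerate(doc["indicators"])
    )
    options = doc.get("options", {})
    if not isinstance(options, dict):
        raise ConfigError(f"{source}: 'options' must be an object")
    allowed_opts = {
        "normalization_mode",
        "ampi_direction",
        "composite_level",
        "reference_values",
    }
    unknown = set(options) - allowed_opts
    if unknown:
        raise ConfigError(f"{source}: unknown option(s) {sorted(unknown)}")
    refs = options.get("reference_values")
    if refs is not None:
        if not isinstance(refs, dict):
            raise ConfigError(f"{source}: reference_values must be an object")
        refs = {str(k): float(v) for k, v in refs.items()}
    return IndexConfig(
        indicators=indicators,
        normalization_mode=options.get("normalization_mode", "minmax"),
        ampi_direction=options.get("ampi_direction", "minus"),
        composite_level=options.get("composite_level", "pillars"),
        reference_values=refs,
    )


def load_index_config(path_or_name: str | Path) -> IndexConfig:
    """Load a validated :class:`IndexConfig` from JSON or by built-in name.

    ``load_index_config("eswb2015")`` returns the built-in 23-indicator
    configuration; any other argument is treated as a filesystem path.
    """
    name = str(path_or_name)
    if name in _BUILTIN_CONFIGS:
        text = (
            resources.files("cihkit.data").joinpath(f"{name}.json").read_text("utf-8")
        )
        return _config_from_document(json.loads(text), source=name)
    path = Path(path_or_name)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        doc = json.loads(path.read_text("utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    return _config_from_document(doc, source=str(path))


def eswb2015() -> IndexConfig:
    """The built-in equitable-and-sustainable well-being configuration."""
    return load_index_config("eswb2015")
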