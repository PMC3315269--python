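"""Screening configuration: component ranges, indicator mapping, options.

A configuration is a YAML or JSON document with two blocks::

    components:           # optional; defaults give the 10/5/5/3/3 ranges
      exposures: {group: pollution_burden, max_score: 10}
      ...
    indicators:           # required
      - id: ozone
        display_name: Ozone concentrations
        component: exposures
        higher_is_worse: true
      ...
    reference_table: statewide.csv      # optional
    redundancy_threshold: 0.8           # optional
    round_display: {component: 1, cumulative: 0}   # optional
    anonymize_units: false              # optional

Validation is collect-all: a single run reports every violation found.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .model import (
    COMPONENT_IDS,
    ComponentSpec,
    IndicatorDefinition,
    default_component_specs,
    validate_component_specs,
)

_DEFAULT_ROUND = {"component": 1, "cumulative": 0}


@dataclass
class ScreeningConfig:
    component_specs: dict[str, ComponentSpec]
    indicator_definitions: list[IndicatorDefinition]
    reference_table: Path | None = None
    redundancy_threshold: float = 0.8
    round_display: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_ROUND))
    anonymize_units: bool = False
    #: distribution family per indicator, used only by the synthetic generator
    indicator_shapes: dict[str, str] = field(default_factory=dict)

    def indicators_for(self, component_id: str) -> list[IndicatorDefinition]:
        return [d for d in self.indicator_definitions if d.component == component_id]

    def validate(self) -> list[str]:
        """Return warnings (components without indicators); raise on hard errors."""
        problems = validate_component_specs(self.component_specs)
        seen: set[str] = set()
        for d in self.indicator_definitions:
            if d.id in seen:
                problems.append(f"duplicate indicator id {d.id!r}")
            seen.add(d.id)
            if d.component not in self.component_specs:
                problems.append(
                    f"indicator {d.id!r} assigned to unknown component {d.component!r}"
                )
        if not self.indicator_definitions:
            problems.append("configuration defines no indicators")
        if not 0.0 <= self.redundancy_threshold <= 1.0:
            problems.append(
                f"redundancy_threshold must be in [0, 1], got {self.redundancy_threshold}"
            )
        if problems:
            raise ConfigurationError(problems)
        warnings = [
            f"component {cid!r} has no indicator configured"
            for cid in self.component_specs
            if not self.indicators_for(cid)
        ]
        return warnings

    @property
    def min_cumulative(self) -> float:
        return self._bound(min_side=True)

    @property
    def max_cumulative(self) -> float:
        return self._bound(min_side=False)

    def _bound(self, min_side: bool) -> float:
        from .model import POLLUTION_BURDEN

        burden = popchar = 0.0
        for s in self.component_specs.values():
            v = s.min_score if min_side else s.max_score
            if s.group == POLLUTION_BURDEN:
                burden += v
            else:
                popchar += v
        return burden * popchar


def _parse_components(block, problems: list[str]) -> dict[str, ComponentSpec]:
    defaults = default_component_specs()
    if block is None:
        return defaults
    if not isinstance(block, dict):
        problems.append("'components' must be a mapping of component id -> settings")
        return defaults
    specs: dict[str, ComponentSpec] = {}
    for cid, raw in block.items():
        if cid not in COMPONENT_IDS:
            problems.append(f"unknown component id {cid!r}")
            continue
        raw = raw or {}
        group = raw.get("group", defaults[cid].group)
        max_score = raw.get("max_score", defaults[cid].max_score)
        if not isinstance(max_score, int) or isinstance(max_score, bool) or max_score < 2:
            problems.append(f"component {cid!r}: max_score must be an integer >= 2, got {max_score!r}")
            continue
        try:
            specs[cid] = ComponentSpec(id=cid, group=group, max_score=max_score)
        except ConfigurationError as e:
            problems.extend(e.problems)
    for cid in COMPONENT_IDS:  # unmentioned components keep their defaults
        specs.setdefault(cid, defaults[cid])
    return specs


def _parse_indicators(block, problems: list[str]) -> list[IndicatorDefinition]:
    defs: list[IndicatorDefinition] = []
    if not isinstance(block, list) or not block:
        problems.append("'indicators' must be a non-empty list")
        return defs
    for k, raw in enumerate(block):
        if not isinstance(raw, dict):
            problems.append(f"indicator entry #{k + 1} is not a mapping")
            continue
        ind_id = raw.get("id")
        comp = raw.get("component")
        hiw = raw.get("higher_is_worse", True)
        entry_problems = []
        if not ind_id or not isinstance(ind_id, str):
            entry_problems.append(f"indicator entry #{k + 1}: missing or invalid 'id'")
        if not comp or comp not in COMPONENT_IDS:
            entry_problems.append(
                f"indicator {ind_id or '#%d' % (k + 1)!s}: component {comp!r} "
                f"is not one of {COMPONENT_IDS}"
            )
        if not isinstance(hiw, bool):
            entry_problems.append(
                f"indicator {ind_id or '#%d' % (k + 1)!s}: higher_is_worse must be boolean, "
                f"got {hiw!r}"
            )
        if entry_problems:
            problems.extend(entry_problems)
            continue
        defs.append(
            IndicatorDefinition(
                id=ind_id,
                component=comp,
                display_name=raw.get("display_name", ind_id),
                higher_is_worse=hiw,
            )
        )
    return defs


def parse_config(doc: dict) -> ScreeningConfig:
    """Build a validated ScreeningConfig from an already-parsed document."""
    if not isinstance(doc, dict):
        raise ConfigurationError(["configuration root must be a mapping"])
    problems: list[str] = []
    specs = _parse_components(doc.get("components"), problems)
    defs = _parse_indicators(doc.get("indicators"), problems)
    shapes = doc.get("indicator_shapes") or {}
    if not isinstance(shapes, dict):
        problems.append("'indicator_shapes' must be a mapping indicator id -> family tag")
        shapes = {}
    round_display = dict(_DEFAULT_ROUND)
    round_display.update(doc.get("round_display") or {})
    ref = doc.get("reference_table")
    cfg = ScreeningConfig(
        component_specs=specs,
        indicator_definitions=defs,
        reference_table=Path(ref) if ref else None,
        redundancy_threshold=doc.get("redundancy_threshold", 0.8),
        round_display=round_display,
        anonymize_units=bool(doc.get("anonymize_units", False)),
        indicator_shapes={str(k): str(v) for k, v in shapes.items()},
    )
    if problems:
        # merge structural problems with whatever validate() finds
        try:
            cfg.validate()
        except ConfigurationError as e:
            problems.extend(p for p in e.problems if p not in problems)
        raise ConfigurationError(problems)
    cfg.validate()
    return cfg


def read_config(path: str | Path) -> ScreeningConfig:
    """Read and validate a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError([f"configuration file not found: {path}"])
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as e:
        raise ConfigurationError([f"cannot parse {path}: {e}"]) from e
    return parse_config(doc)


#: Table of the pilot's 16 indicators: (id, display name, component,
#: higher_is_worse, synthetic distribution family).
PILOT_INDICATORS = [
    ("pm25", "PM2.5 concentrations", "exposures", True, "skewed_positive"),
    ("ozone", "Ozone concentrations", "exposures", True, "skewed_positive"),
    ("toxic_releases", "Toxic releases from industrial facilities", "exposures", True, "skewed_positive"),
    ("traffic", "Traffic volumes", "exposures", True, "skewed_positive"),
    ("pesticide_use", "Pesticide use", "exposures", True, "skewed_positive"),
    ("low_birth_weight", "Low birth weight rate", "public_health_effects", True, "rate"),
    ("heart_disease_mortality", "Heart disease mortality rate", "public_health_effects", True, "rate"),
    ("cancer_mortality", "Cancer mortality rate", "public_health_effects", True, "rate"),
    ("asthma_hospitalization", "Asthma hospitalization rate", "public_health_effects", True, "rate"),
    ("hazardous_waste_sites", "Hazardous waste and clean-up sites", "environmental_effects", True, "count"),
    ("leaking_tanks", "Leaking underground fuel tanks", "environmental_effects", True, "count"),
    ("pct_under_5", "Percent under age 5", "sensitive_populations", True, "proportion"),
    ("pct_over_65", "Percent over age 65", "sensitive_populations", True, "proportion"),
    ("pct_less_hs", "Percent with less than high school education", "socioeconomic_factors", True, "proportion"),
    ("median_income", "Median household income", "socioeconomic_factors", False, "skewed_positive"),
    ("pct_poverty", "Percent below 2x poverty level", "socioeconomic_factors", True, "proportion"),
]


def pilot_config() -> ScreeningConfig:
    """The 16-indicator configuration mirroring the pilot screen's structure.

    Five exposure, four public-health, two environmental, two sensitive-
    population and three socioeconomic indicators; median household income
    is the one beneficial (higher_is_worse = false) indicator.
    """
    cfg = ScreeningConfig(
        component_specs=default_component_specs(),
        indicator_definitions=[
            IndicatorDefinition(id=i, display_name=n, component=c, higher_is_worse=h)
            for i, n, c, h, _ in PILOT_INDICATORS
        ],
        indicator_shapes={i: s for i, _, _, _, s in PILOT_INDICATORS},
    )
    cfg.validate()
    return cfg


def write_config(cfg: ScreeningConfig, path: str | Path) -> None:
    """Serialize a configuration back to YAML (round-trips through read_config)."""
    doc = {
        "components": {
            cid: {"group": s.group, "max_score": s.max_score}
            for cid, s in cfg.component_specs.items()
        },
        "indicators": [
            {
                "id": d.id,
                "display_name": d.display_name,
                "component": d.component,
                "higher_is_worse": d.higher_is_worse,
            }
            for d in cfg.indicator_definitions
        ],
        "redundancy_threshold": cfg.redundancy_threshold,
        "round_display": cfg.round_display,
        "anonymize_units": cfg.anonymize_units,
    }
    if cfg.indicator_shapes:
        doc["indicator_shapes"] = cfg.indicator_shapes
    if cfg.reference_table:
        doc["reference_table"] = str(cfg.reference_table)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
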