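"""Domain types for cumulative-impact screening.

The screening method scores geographic units (ZIP codes, census tracts, ...)
on five components arranged in two groups:

* **pollution burden** — exposures, public health effects, environmental
  effects; their component scores are summed;
* **population characteristics** — sensitive populations, socioeconomic
  factors; summed, and used as a multiplier on pollution burden.

Each component score is the average of one or more indicator scores; each
indicator score is an integer bin (decile, quintile or tertile by default)
derived from the unit's percentile rank within a reference distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputDataError

POLLUTION_BURDEN = "pollution_burden"
POPULATION_CHARACTERISTICS = "population_characteristics"

GROUPS = (POLLUTION_BURDEN, POPULATION_CHARACTERISTICS)

#: canonical component ids in presentation order
COMPONENT_IDS = (
    "exposures",
    "public_health_effects",
    "environmental_effects",
    "sensitive_populations",
    "socioeconomic_factors",
)

_DEFAULT_GROUP = {
    "exposures": POLLUTION_BURDEN,
    "public_health_effects": POLLUTION_BURDEN,
    "environmental_effects": POLLUTION_BURDEN,
    "sensitive_populations": POPULATION_CHARACTERISTICS,
    "socioeconomic_factors": POPULATION_CHARACTERISTICS,
}

_DEFAULT_MAX_SCORE = {
    "exposures": 10,
    "public_health_effects": 5,
    "environmental_effects": 5,
    "sensitive_populations": 3,
    "socioeconomic_factors": 3,
}


@dataclass(frozen=True)
class ComponentSpec:
    """One of the five scored components and its bin range.

    ``min_score`` is always 1; ``max_score`` is the bin count (10 for
    exposures, 5 for the two effects components, 3 for the population
    components under the default weighting, but overridable in config).
    """

    id: str
    group: str
    max_score: int
    min_score: int = 1

    def __post_init__(self) -> None:
        if self.id not in COMPONENT_IDS:
            raise ConfigurationError(
                [f"unknown component id {self.id!r}; expected one of {COMPONENT_IDS}"]
            )
        if self.group not in GROUPS:
            raise ConfigurationError(
                [f"component {self.id!r}: unknown group {self.group!r}"]
            )
        if self.min_score != 1:
            raise ConfigurationError([f"component {self.id!r}: min_score must be 1"])
        if self.max_score < 2:
            raise ConfigurationError(
                [f"component {self.id!r}: max_score must be >= 2, got {self.max_score}"]
            )


def default_component_specs() -> dict[str, ComponentSpec]:
    """The standard five-component, two-group layout with 10/5/5/3/3 ranges."""
    return {
        cid: ComponentSpec(id=cid, group=_DEFAULT_GROUP[cid], max_score=_DEFAULT_MAX_SCORE[cid])
        for cid in COMPONENT_IDS
    }


def validate_component_specs(specs: dict[str, ComponentSpec]) -> list[str]:
    """Structural checks: exactly five components, three burden + two population."""
    problems: list[str] = []
    if set(specs) != set(COMPONENT_IDS):
        problems.append(
            f"component set must be exactly {sorted(COMPONENT_IDS)}, got {sorted(specs)}"
        )
        return problems
    n_burden = sum(1 for s in specs.values() if s.group == POLLUTION_BURDEN)
    if n_burden != 3:
        problems.append(
            f"expected 3 components in {POLLUTION_BURDEN} and 2 in "
            f"{POPULATION_CHARACTERISTICS}, got {n_burden} and {5 - n_burden}"
        )
    return problems


@dataclass(frozen=True)
class IndicatorDefinition:
    """A single measured quantity feeding one component.

    ``higher_is_worse`` declares the direction: True for e.g. ozone
    concentration (more pollution, more impact), False for beneficial
    measures such as median household income, which are reflected before
    binning so that affluence lowers, not raises, the impact score.
    """

    id: str
    component: str
    display_name: str = ""
    higher_is_worse: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ConfigurationError(["indicator id must be non-empty"])
        if not self.display_name:
            object.__setattr__(self, "display_name", self.id)


@dataclass(frozen=True)
class ReferenceDistribution:
    """The pool of values an indicator is percentile-ranked against.

    Ideally the complete statewide distribution; may be a superset of the
    scored units. Stored sorted; NaNs are dropped at construction.
    """

    indicator_id: str
    sorted_values: np.ndarray

    @classmethod
    def from_values(cls, indicator_id: str, values) -> "ReferenceDistribution":
        arr = np.asarray(values, dtype=float).ravel()
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise ConfigurationError(
                [f"reference for {indicator_id!r} needs at least 2 finite values, got {arr.size}"]
            )
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError(
                [f"reference for {indicator_id!r} contains non-finite values"]
            )
        return cls(indicator_id=indicator_id, sorted_values=np.sort(arr))

    @property
    def n(self) -> int:
        return int(self.sorted_values.size)


@dataclass
class IndicatorValueMatrix:
    """Units x indicators table of raw measurements; NaN marks missing."""

    unit_ids: list[str]
    indicator_ids: list[str]
    values: np.ndarray  # shape (n_units, n_indicators), float, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.unit_ids), len(self.indicator_ids)):
            raise InputDataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.unit_ids)} units x {len(self.indicator_ids)} indicators"
            )
        if len(set(self.unit_ids)) != len(self.unit_ids):
            dupes = sorted({u for u in self.unit_ids if self.unit_ids.count(u) > 1})
            raise InputDataError(f"duplicate unit_id(s): {', '.join(dupes)}")
        if len(set(self.indicator_ids)) != len(self.indicator_ids):
            raise InputDataError("duplicate indicator ids in matrix")
        with np.errstate(invalid="ignore"):
            bad = np.isinf(self.values)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise InputDataError(
                f"non-finite value at unit {self.unit_ids[i]!r}, "
                f"indicator {self.indicator_ids[j]!r}"
            )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def column(self, indicator_id: str) -> np.ndarray:
        try:
            j = self.indicator_ids.index(indicator_id)
        except ValueError:
            raise InputDataError(f"indicator {indicator_id!r} not in matrix") from None
        return self.values[:, j]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.unit_ids, columns=self.indicator_ids)


@dataclass
class ScoreCard:
    """Complete scoring record for one geographic unit."""

    unit_id: str
    indicator_scores: dict[str, int | None]
    component_scores: dict[str, float]
    pollution_burden: float
    population_characteristics: float
    cumulative_impact: float

    def check(self, specs: dict[str, ComponentSpec], tol: float = 1e-12) -> None:
        """Raise if the decomposition identity or any range is violated."""
        for cid, s in self.component_scores.items():
            spec = specs[cid]
            if not (spec.min_score - tol <= s <= spec.max_score + tol):
                raise ValueError(f"{self.unit_id}: component {cid} score {s} out of range")
        burden = sum(
            s for cid, s in self.component_scores.items() if specs[cid].group == POLLUTION_BURDEN
        )
        popchar = sum(
            s
            for cid, s in self.component_scores.items()
            if specs[cid].group == POPULATION_CHARACTERISTICS
        )
        if not math.isclose(burden, self.pollution_burden, abs_tol=tol):
            raise ValueError(f"{self.unit_id}: pollution burden mismatch")
        if not math.isclose(popchar, self.population_characteristics, abs_tol=tol):
            raise ValueError(f"{self.unit_id}: population characteristics mismatch")
        if not math.isclose(
            self.pollution_burden * self.population_characteristics,
            self.cumulative_impact,
            abs_tol=tol,
        ):
            raise ValueError(f"{self.unit_id}: cumulative impact is not the group product")


@dataclass
class ExcludedUnit:
    """A unit dropped from ranking, with a machine-readable reason code."""

    unit_id: str
    reason_code: str
    detail: str = ""


@dataclass
class ScoringResult:
    """Outcome of scoring a matrix: ranked-able cards plus exclusions."""

    cards: list[ScoreCard]
    excluded: list[ExcludedUnit] = field(default_factory=list)
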