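"""Scoring mathematics for the cumulative-impact screen.

The pipeline per unit is:

1. each indicator value is percentile-ranked (mid-rank rule) within its
   reference distribution and binned into 1..max integer scores, with the
   bin count set by the indicator's component (10/5/5/3/3 by default);
2. indicator scores within a component are averaged (unrounded);
3. pollution burden = exposures + public health effects + environmental
   effects; population characteristics = sensitive populations +
   socioeconomic factors;
4. cumulative impact = pollution burden x population characteristics,
   spanning 6-120 under the default ranges.

Everything is rank-based: any strictly increasing transform applied to an
indicator column together with its reference leaves all scores unchanged.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InputDataError
from .model import (
    POLLUTION_BURDEN,
    POPULATION_CHARACTERISTICS,
    ComponentSpec,
    ExcludedUnit,
    IndicatorDefinition,
    IndicatorValueMatrix,
    ReferenceDistribution,
    ScoreCard,
    ScoringResult,
    validate_component_specs,
)

__all__ = [
    "percentile_rank",
    "bin_score",
    "component_score",
    "pollution_burden_score",
    "population_characteristics_score",
    "cumulative_impact",
    "score_units",
    "rank_units",
    "top_contributors",
    "indicator_redundancy",
    "RedundancyPair",
]

_TINY = 1e-12  # lower clamp keeping percentiles inside (0, 1]


def percentile_rank(value: float, reference: ReferenceDistribution) -> float:
    """Mid-rank percentile of ``value`` within ``reference``.

    Returns ``(c_below + 0.5 * c_equal) / n`` clamped into (0, 1], where
    ``c_below`` and ``c_equal`` count reference values strictly below and
    equal to ``value``. The mid-rank rule is tie-symmetric: a value equal
    to every reference value ranks exactly 0.5. Values below the reference
    minimum map near 0; values above the maximum map to 1.
    """
    if not math.isfinite(value):
        raise InputDataError(f"cannot rank non-finite value {value!r}")
    sv = reference.sorted_values
    n = reference.n
    lo = bisect_left(sv, value)
    hi = bisect_right(sv, value)
    p = (lo + 0.5 * (hi - lo)) / n
    return min(max(p, _TINY), 1.0)


def bin_score(
    value: float,
    reference: ReferenceDistribution,
    n_bins: int,
    higher_is_worse: bool = True,
) -> int:
    """Equal-count bin score in 1..n_bins for ``value`` against ``reference``.

    The mid-rank percentile is computed, reflected (p -> 1 - p) for
    beneficial indicators so that the *best* raw value scores 1, then mapped
    to ``ceil(p * n_bins)`` clamped into [1, n_bins]. With distinct values
    and n divisible by n_bins this produces exact equal-count deciles /
    quintiles / tertiles: one n_bins-th of the pool lands in each bin.
    """
    if n_bins < 2:
        raise ConfigurationError([f"n_bins must be >= 2, got {n_bins}"])
    p = percentile_rank(value, reference)
    if not higher_is_worse:
        p = min(max(1.0 - p, _TINY), 1.0)
    return min(max(math.ceil(p * n_bins), 1), n_bins)


def component_score(indicator_scores: list[int | None]) -> float:
    """Arithmetic mean of the non-missing indicator scores, unrounded.

    Raises ``ValueError`` when every score is missing; callers treat that
    as an excluded unit, not a crash.
    """
    present = [s for s in indicator_scores if s is not None]
    if not present:
        raise ValueError("all indicator scores missing for component")
    return float(sum(present)) / len(present)


def pollution_burden_score(exposures: float, public_health: float, environmental: float) -> float:
    """Sum of the three pollution-burden component scores (3-20 by default)."""
    return exposures + public_health + environmental


def population_characteristics_score(sensitive: float, socioeconomic: float) -> float:
    """Sum of the two population-characteristics component scores (2-6 by default)."""
    return sensitive + socioeconomic


def cumulative_impact(pollution_burden: float, population_characteristics: float) -> float:
    """The multiplicative index: burden x population characteristics (6-120)."""
    return pollution_burden * population_characteristics


def score_units(
    matrix: IndicatorValueMatrix,
    definitions: list[IndicatorDefinition],
    references: dict[str, ReferenceDistribution],
    specs: dict[str, ComponentSpec],
) -> ScoringResult:
    """Score every unit in ``matrix``, producing one ScoreCard per unit.

    Deterministic for fixed inputs. Units whose every indicator within some
    component is missing cannot be given a component score without
    imputation and are returned as exclusions with reason code
    ``component_missing`` instead of cards.
    """
    problems = validate_component_specs(specs)
    defs_by_id = {d.id: d for d in definitions}
    for ind in matrix.indicator_ids:
        if ind not in defs_by_id:
            problems.append(f"indicator {ind!r} has no definition")
        elif defs_by_id[ind].component not in specs:
            problems.append(
                f"indicator {ind!r} maps to unknown component {defs_by_id[ind].component!r}"
            )
        if ind not in references:
            problems.append(f"indicator {ind!r} has no reference distribution")
    comp_indicators: dict[str, list[str]] = {cid: [] for cid in specs}
    for ind in matrix.indicator_ids:
        d = defs_by_id.get(ind)
        if d is not None and d.component in comp_indicators:
            comp_indicators[d.component].append(ind)
    for cid, inds in comp_indicators.items():
        if not inds:
            problems.append(f"component {cid!r} has no indicator in the matrix")
    if problems:
        raise ConfigurationError(problems)

    # Pre-bin column by column: every unit in a column shares one reference.
    col_scores: dict[str, list[int | None]] = {}
    for ind in matrix.indicator_ids:
        d = defs_by_id[ind]
        ref = references[ind]
        nb = specs[d.component].max_score
        col = matrix.column(ind)
        col_scores[ind] = [
            None if np.isnan(v) else bin_score(float(v), ref, nb, d.higher_is_worse)
            for v in col
        ]

    cards: list[ScoreCard] = []
    excluded: list[ExcludedUnit] = []
    for i, unit in enumerate(matrix.unit_ids):
        ind_scores = {ind: col_scores[ind][i] for ind in matrix.indicator_ids}
        comp_scores: dict[str, float] = {}
        missing_comps: list[str] = []
        for cid, inds in comp_indicators.items():
            try:
                comp_scores[cid] = component_score([ind_scores[x] for x in inds])
            except ValueError:
                missing_comps.append(cid)
        if missing_comps:
            excluded.append(
                ExcludedUnit(
                    unit_id=unit,
                    reason_code="component_missing",
                    detail="no indicator data for: " + ", ".join(sorted(missing_comps)),
                )
            )
            continue
        burden = sum(s for cid, s in comp_scores.items() if specs[cid].group == POLLUTION_BURDEN)
        popchar = sum(
            s for cid, s in comp_scores.items() if specs[cid].group == POPULATION_CHARACTERISTICS
        )
        cards.append(
            ScoreCard(
                unit_id=unit,
                indicator_scores=ind_scores,
                component_scores=comp_scores,
                pollution_burden=burden,
                population_characteristics=popchar,
                cumulative_impact=cumulative_impact(burden, popchar),
            )
        )
    return ScoringResult(cards=cards, excluded=excluded)


def rank_units(cards: list[ScoreCard]) -> list[tuple[int, ScoreCard]]:
    """Order cards from highest to lowest cumulative impact.

    Ties share the minimum rank of their block ("1224" ranking) and are
    secondarily ordered by unit_id so output is deterministic.
    """
    if not cards:
        raise InputDataError("cannot rank an empty set of score cards")
    ordered = sorted(cards, key=lambda c: (-c.cumulative_impact, c.unit_id))
    ranked: list[tuple[int, ScoreCard]] = []
    for pos, card in enumerate(ordered, start=1):
        if ranked and card.cumulative_impact == ranked[-1][1].cumulative_impact:
            ranked.append((ranked[-1][0], card))
        else:
            ranked.append((pos, card))
    return ranked


def top_contributors(
    card: ScoreCard, specs: dict[str, ComponentSpec]
) -> list[tuple[str, float]]:
    """Components ordered by normalized contribution to the unit's score.

    Components span different ranges (1-10 vs 1-3), so raw scores are not
    comparable; each is mapped to (score - 1) / (max - 1) in [0, 1] before
    sorting descending. Ties keep the canonical component order.
    """
    normalized = [
        (cid, (card.component_scores[cid] - specs[cid].min_score)
         / (specs[cid].max_score - specs[cid].min_score))
        for cid in card.component_scores
    ]
    order = {cid: k for k, cid in enumerate(card.component_scores)}
    return sorted(normalized, key=lambda t: (-t[1], order[t[0]]))


class RedundancyPair:
    """Spearman correlation between two indicator columns, with a flag."""

    __slots__ = ("indicator_a", "indicator_b", "rho", "n_pairs", "flagged", "evaluable")

    def __init__(self, indicator_a, indicator_b, rho, n_pairs, flagged, evaluable):
        self.indicator_a = indicator_a
        self.indicator_b = indicator_b
        self.rho = rho
        self.n_pairs = n_pairs
        self.flagged = flagged
        self.evaluable = evaluable

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        r = "n/a" if self.rho is None else f"{self.rho:+.3f}"
        return f"RedundancyPair({self.indicator_a}, {self.indicator_b}, rho={r})"


def indicator_redundancy(
    matrix: IndicatorValueMatrix, threshold: float = 0.8
) -> list[RedundancyPair]:
    """Flag indicator pairs that may measure the same underlying quantity.

    Computes the pairwise-complete Spearman rank correlation for every
    unordered indicator pair and flags those with ``|rho| >= threshold``.
    Pairs with fewer than 3 complete observations are reported as
    not-evaluable rather than raising.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError([f"redundancy threshold must be in [0, 1], got {threshold}"])
    out: list[RedundancyPair] = []
    ids = matrix.indicator_ids
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            xa = matrix.values[:, a_idx]
            xb = matrix.values[:, b_idx]
            ok = ~(np.isnan(xa) | np.isnan(xb))
            n_pairs = int(ok.sum())
            if n_pairs < 3:
                out.append(RedundancyPair(ids[a_idx], ids[b_idx], None, n_pairs, False, False))
                continue
            rho = stats.spearmanr(xa[ok], xb[ok]).statistic
            if np.isnan(rho):  # constant column: correlation undefined
                out.append(RedundancyPair(ids[a_idx], ids[b_idx], None, n_pairs, False, False))
                continue
            rho = float(rho)
            out.append(
                RedundancyPair(ids[a_idx], ids[b_idx], rho, n_pairs, abs(rho) >= threshold, True)
            )
    return out
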