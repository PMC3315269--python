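"""Synthetic "state" generator for end-to-end testing of the screen.

Real statewide indicator data (air monitoring, vital statistics, census
tables) cannot ship with the package, so this module fabricates a state of
geographic units whose indicators are mutually correlated through a single
hidden per-unit *latent burden*. Because the screening method is purely
rank-based, realism of the marginal distributions only affects plausibility,
never correctness; what matters is that

* columns have the right shape and support for their quantity type
  (right-skewed positive emissions, nonnegative rates, count tallies,
  bounded percentages),
* a known ground-truth gradient exists, so tests can ask whether the
  cumulative impact score recovers it.

Each unit draws a latent burden ``z ~ N(0, 1)``. Indicator ``j`` mixes the
latent with independent noise, ``w = lam * z + (1 - lam) * eps``, standardizes
``w``, and pushes its normal CDF value through the family's quantile
function. Beneficial indicators (``higher_is_worse = False``) use ``-w`` so
their raw values *decrease* along the burden gradient. Missing cells are
inserted completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import ScreeningConfig
from .errors import ConfigurationError
from .model import IndicatorValueMatrix
from .scoring import ScoreCard

FAMILIES = ("skewed_positive", "rate", "count", "proportion")

# Marginal parameters per family, chosen for plausibility of the pilot's
# quantity types (annual tons released, deaths per 100k, site counts,
# population percentages). Only ranks reach the scoring pipeline.
_FAMILY_PARAMS = {
    "skewed_positive": {"mu": 2.0, "sigma": 1.0},       # log-normal
    "rate": {"shape": 4.0, "scale": 25.0},              # gamma, mean 100
    "count": {"mu": 6.0},                               # Poisson
    "proportion": {"loc": -1.5, "scale": 0.8},          # logit-normal x 100
}


@dataclass
class SyntheticStateSpec:
    """Parameters of the generated state.

    n_units
        Number of geographic units; the pilot screened 30.
    seed
        Seed for the generator; identical spec + seed gives bit-identical
        output.
    latent_correlation
        In [0, 1]; 0 makes indicators mutually independent, 1 makes every
        indicator a monotone transform of the latent burden.
    missing_rate
        Probability, in [0, 0.5), that any one cell is blanked (MCAR).
    indicator_shapes
        Family tag per indicator; defaults come from the screening config.
    """

    n_units: int = 30
    seed: int = 0
    latent_correlation: float = 0.5
    missing_rate: float = 0.0
    indicator_shapes: dict[str, str] = field(default_factory=dict)

    def validate(self, config: ScreeningConfig) -> dict[str, str]:
        problems = []
        if self.n_units < 10:
            problems.append(f"n_units must be >= 10, got {self.n_units}")
        if not 0.0 <= self.latent_correlation <= 1.0:
            problems.append(
                f"latent_correlation must be in [0, 1], got {self.latent_correlation}"
            )
        if not 0.0 <= self.missing_rate < 0.5:
            problems.append(f"missing_rate must be in [0, 0.5), got {self.missing_rate}")
        shapes = dict(config.indicator_shapes)
        shapes.update(self.indicator_shapes)
        for d in config.indicator_definitions:
            fam = shapes.get(d.id)
            if fam is None:
                problems.append(f"indicator {d.id!r} has no distribution family tag")
            elif fam not in FAMILIES:
                problems.append(
                    f"indicator {d.id!r}: unknown family {fam!r}; expected one of {FAMILIES}"
                )
        if problems:
            raise ConfigurationError(problems)
        return shapes


@dataclass
class SyntheticState:
    """A generated state: the indicator matrix plus the hidden ground truth."""

    matrix: IndicatorValueMatrix
    latent_burden: dict[str, float]
    spec: SyntheticStateSpec


def _marginal(family: str, u: np.ndarray) -> np.ndarray:
    p = _FAMILY_PARAMS[family]
    if family == "skewed_positive":
        return np.exp(p["mu"] + p["sigma"] * stats.norm.ppf(u))
    if family == "rate":
        return stats.gamma.ppf(u, a=p["shape"], scale=p["scale"])
    if family == "count":
        return stats.poisson.ppf(u, mu=p["mu"])
    if family == "proportion":
        return 100.0 / (1.0 + np.exp(-(p["loc"] + p["scale"] * stats.norm.ppf(u))))
    raise ConfigurationError([f"unknown distribution family {family!r}"])


def generate_state(spec: SyntheticStateSpec, config: ScreeningConfig) -> SyntheticState:
    """Generate a synthetic state for the given screening configuration."""
    shapes = spec.validate(config)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_units
    lam = spec.latent_correlation
    z = rng.standard_normal(n)
    unit_ids = [f"U{k:05d}" for k in range(n)]
    cols = []
    # w = lam*z + (1-lam)*eps has sd sqrt(lam^2 + (1-lam)^2); standardize so
    # the normal CDF step yields uniform ranks at every lam.
    sd = float(np.hypot(lam, 1.0 - lam))
    for d in config.indicator_definitions:
        eps = rng.standard_normal(n)
        w = (lam * z + (1.0 - lam) * eps) / (sd if sd > 0 else 1.0)
        if not d.higher_is_worse:
            w = -w
        # keep u strictly inside (0,1) for the quantile functions
        u = np.clip(stats.norm.cdf(w), 1e-12, 1.0 - 1e-12)
        cols.append(_marginal(shapes[d.id], u))
    values = np.column_stack(cols)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.copy()
        values[mask] = np.nan
    matrix = IndicatorValueMatrix(
        unit_ids=unit_ids,
        indicator_ids=[d.id for d in config.indicator_definitions],
        values=values,
    )
    return SyntheticState(
        matrix=matrix,
        latent_burden={u_id: float(zz) for u_id, zz in zip(unit_ids, z)},
        spec=spec,
    )


def recovery_check(state: SyntheticState, cards: list[ScoreCard]) -> float | None:
    """Spearman correlation between latent burden and cumulative impact.

    Measures how well the screen's final ranking recovers the hidden
    gradient that generated the data. Returns None when fewer than 3 units
    are comparable (e.g. after exclusions).
    """
    pairs = [
        (state.latent_burden[c.unit_id], c.cumulative_impact)
        for c in cards
        if c.unit_id in state.latent_burden
    ]
    if len(pairs) < 3:
        return None
    lat, imp = zip(*pairs)
    return float(stats.spearmanr(lat, imp).statistic)
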