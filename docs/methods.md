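# Methods

## The screening model

`ciscreen` implements a relative cumulative-impact screen for geographic
units (ZIP codes in the motivating pilot; census tracts, cities or counties
in general). The screen combines five components arranged in two groups:

| Group | Component | Default score range |
|---|---|---|
| Pollution burden | Exposures | 1–10 |
| Pollution burden | Public health effects | 1–5 |
| Pollution burden | Environmental effects | 1–5 |
| Population characteristics | Sensitive populations | 1–3 |
| Population characteristics | Socioeconomic factors | 1–3 |

For a unit *u* with component scores *C₁…C₅*:

```
pollution_burden(u)            = C_exp + C_health + C_env          ∈ [3, 20]
population_characteristics(u)  = C_sens + C_socio                  ∈ [2, 6]
cumulative_impact(u)           = pollution_burden(u)
                                 × population_characteristics(u)   ∈ [6, 120]
```

The multiplier structure encodes the assumption that population
sensitivity and socioeconomic vulnerability *modify* the effect of
pollution burden rather than add to it, mirroring how risk assessment
applies sensitivity multipliers for children and other susceptible groups.
The asymmetric ranges encode a deliberate weighting: exposures data are
the richest and most actionable (10 bins), effects data are noisier (5),
and population characteristics act as a bounded several-fold modifier (3).
All ranges are configurable; the 6–120 bound is recomputed from the
configuration, never hard-coded.

The output is a *ranking* tool. Scores are comparative positions within a
reference population, not absolute risk estimates; a score of 96 means
"near the top of the screened range", not a quantified health impact.

## Indicator scoring (rank binning)

Each indicator value is scored by where it falls in a **reference
distribution** — ideally the complete statewide distribution, optionally
just the scored units themselves (in which case a warning is logged). The
rule, for a reference of size *n* and a component with *k* bins:

1. mid-rank percentile `p = (c_below + 0.5·c_equal) / n`, clamped into
   (0, 1], where `c_below`/`c_equal` count reference values strictly below
   / equal to the unit's value;
2. for *beneficial* indicators (`higher_is_worse: false`, e.g. median
   household income) reflect `p ← 1 − p`, so affluence lowers rather than
   raises the score — with mid-ranks, `1 − p` is exactly the mid-rank of
   the value in the sign-flipped reference;
3. bin score `s = ceil(p·k)` clamped into [1, k].

Design notes on this rule:

* **Ties.** The mid-rank rule is deterministic and tie-symmetric: a value
  equal to every reference value scores the middle bin. A heavy zero mass
  (pesticide use in urban ZIP codes) therefore lands in one middle-low bin
  rather than being split arbitrarily; no special-casing is needed.
* **Equal counts.** With all values distinct and *n* divisible by *k*,
  exactly *n/k* units land in each bin — exact deciles/quintiles/tertiles.
* **Out-of-pool values.** Values below the reference minimum clamp to bin
  1, above the maximum to bin *k*; scoring a unit against a superset
  reference pool is therefore always well defined.
* **Reflection edge.** The identity `s(v, k, beneficial) = k+1 −
  s(v, k, harmful)` holds on distinct references whenever `p·k` is not an
  exact integer. It can fail by one bin only in the degenerate case where
  the bin count exceeds sensible use (e.g. 10 bins over a 5-value
  reference, where `p·k` hits integers). With bin counts at or below the
  reference size and the default 10/5/3 bin counts against pools of
  realistic size this does not occur.

Because only ranks enter, every score is invariant under strictly
increasing transforms of an indicator column together with its reference
(unit conversions, log scales), and worsening a unit's raw value can never
lower its cumulative score. Both properties are enforced by tests.

## Aggregation, missing data, rounding, ranking

* A component score is the **unrounded arithmetic mean** of its non-missing
  indicator bin scores. Rounding is display-only (defaults: one decimal
  for components, integer for cumulative impact) because rounding before
  multiplication distorts the ranking.
* A unit missing *every* indicator of some component cannot be scored
  without imputation; it is excluded from ranking and reported in a
  companion file with reason code `component_missing`. Partially missing
  components use the mean of what is present.
* Ranking is descending by cumulative impact, ties sharing the minimum
  rank of their block ("1224" convention) with secondary lexicographic
  order on unit id, so output is identical across runs and platforms.
* Contributor decomposition normalizes each component to
  `(score − 1)/(max − 1)` so components on different ranges are comparable
  when asking which component drives a unit's score.
* Indicator redundancy screening uses pairwise-complete Spearman rank
  correlation; pairs with `|ρ|` at or above the configurable threshold
  (default 0.8) are flagged as potentially duplicating information. Pairs
  with fewer than three complete observations are reported not-evaluable.

## The synthetic state generator

Statewide monitoring, vital-statistics and census data cannot ship with
the package, so testing uses a generated "state". Each unit draws a latent
burden `z ~ N(0,1)`; indicator *j* mixes it with independent noise,
`w = λ·z + (1−λ)·ε`, standardizes *w*, and pushes `Φ(w)` through a
family-specific quantile function:

| Family | Marginal | Used for | Default parameters |
|---|---|---|---|
| `skewed_positive` | log-normal | emissions, traffic, pesticides, income | μ=2, σ=1 |
| `rate` | gamma | health outcome rates | shape 4, scale 25 (mean 100 per 100k) |
| `count` | Poisson | site tallies | mean 6 |
| `proportion` | logit-normal ×100 | demographic percentages | logit-mean −1.5, sd 0.8 |

Beneficial indicators use `−w`, so their raw values decrease along the
burden gradient. Missingness is completely at random at a configurable
rate. Defaults: 30 units (the pilot's size), λ = 0.5, no missingness. The
marginal parameters were fixed once for plausibility of the quantity types;
since the screen is rank-based they affect realism only, not correctness.

What the generator emulates: mutually correlated, right-skewed /
rate-like / count / bounded-percentage indicators over a demographically
diverse set of units, with a known ground-truth gradient. What it does
not: spatial autocorrelation, informative missingness, the actual
California marginals, or indicator-specific correlation structure beyond
the single shared factor. Passing recovery tests therefore show the
*method* ranks a latent gradient correctly under clean conditions, not
that any particular real dataset would be ranked correctly.

`recovery_check` reports the Spearman correlation between latent burden
and cumulative impact. At λ = 1 every indicator is a monotone transform of
the latent, and recovery is near-perfect (ρ > 0.95 at n = 500); at λ = 0 it
is null (|ρ| < 0.15 at n = 2000); mean recovery increases monotonically in
λ (checked over 5 seeds per λ at n = 500). One caveat: Poisson count
columns tie on the integer grid, so their individual rank correlation with
the latent is slightly below 1 even at λ = 1.

## Numerical choices

* Percentiles are clamped into (0, 1] with a 1e−12 floor; the
  decomposition identity `cumulative = burden × popchar` is exact to
  1e−12 and asserted on every card.
* Results CSVs print scores at 12 significant digits, enough for a
  write/read round trip to reproduce every score bit-exactly.
* The scoring path contains no randomness at all; only the generator
  consumes a seed (NumPy `default_rng`), and identical spec + seed gives
  bit-identical output.
* Problem sizes in the test suite (500–2000 synthetic units, 1000-trial
  property suites, exhaustive oracle comparison on references of size ≤ 8
  over a 4-value alphabet) were chosen so the whole suite runs in seconds
  while still exercising every tie and clamping branch.

## Known limitations

* Equal weights across indicators within a component; weighted averaging
  is a plausible extension the config format does not yet express.
* The redundancy check flags pairs but does not deduplicate or reweight;
  resolving overlap is left to the analyst.
* No geography: units are opaque identifiers, and no spatial smoothing or
  boundary handling is provided.
* The screen measures combined multi-stressor burden; a community severely
  impacted by a single stressor can rank modestly by construction.
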