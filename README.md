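# ciscreen

Cumulative-impact screening scores for communities.

Environmental-justice screening asks a comparative question: of the
communities in a state, which carry the greatest *combined* burden of
pollution exposures, pollution-linked health and environmental effects,
and population vulnerability? `ciscreen` implements the standard
burden-times-vulnerability screening index for that question. It is a
ranking tool for analysts at environmental agencies, health departments
and research groups — it orders communities for prioritization; it does
not estimate absolute health risk.

## The model

Each geographic unit (ZIP code, census tract, ...) is scored on five
components in two groups. Every indicator value is percentile-ranked
(mid-rank rule for ties) within a reference distribution — ideally the
complete statewide distribution — and binned into an integer score:
deciles (1–10) for exposures, quintiles (1–5) for public-health and
environmental effects, tertiles (1–3) for sensitive populations and
socioeconomic factors. Indicators carry a direction flag; beneficial ones
such as median household income are reflected before binning. Multiple
indicator scores per component are averaged, unrounded. Then

```
pollution burden            P = C_exposures + C_public_health + C_environmental   ∈ [3, 20]
population characteristics  V = C_sensitive + C_socioeconomic                     ∈ [2, 6]
cumulative impact           I = P × V                                             ∈ [6, 120]
```

The multiplicative form treats population sensitivity and socioeconomic
vulnerability as modifiers of pollution burden, the same way risk
assessment applies sensitivity multipliers for susceptible groups. Units
are ranked descending by *I*; a contributor decomposition normalizes each
component to `(score − 1)/(max − 1)` to show what drives a unit's rank.
See `docs/methods.md` for the full account, including tie handling,
missing-data policy and the synthetic-data generator.

## Worked example

Generate a synthetic 30-unit "state" with the standard 16-indicator
configuration (5 exposure, 4 health, 2 environmental, 2 sensitive-
population, 3 socioeconomic indicators), score it, and render the ranked
shaded report:

```sh
python -c "from ciscreen import pilot_config, write_config; write_config(pilot_config(), 'config.yaml')"
ciscreen simulate --config config.yaml --n-units 30 --seed 12 --out sim
ciscreen score    --config config.yaml --data sim/indicators.csv --out res
ciscreen report   --results res/results.csv --config config.yaml --out rep --anonymize
head -8 rep/report.txt
```

prints

```
scored 30 unit(s), excluded 0; results in res/results.csv
report with 30 row(s) written to rep
Unit  Rank  Exposures  Public health effects  Environmental effects  Sensitive populations  Socioeconomic factors  Pollution burden  Population characteristics  Cumulative impact
----  ----  ---------  ---------------------  ---------------------  ---------------------  ---------------------  ----------------  --------------------------  -----------------
A     1     9.2        4.8                    4.0                    3.0                    3.0                    17.9              6.0                         108
B     2     8.8        4.5                    4.5                    2.0                    3.0                    17.8              5.0                         89
C     3     7.2        3.5                    4.0                    3.0                    3.0                    14.7              6.0                         88
D     4     7.8        3.8                    3.5                    2.5                    3.0                    15.1              5.5                         83
```

Unit A ranks first: it averages 9.2/10 across the five exposure
indicators, holds the maximum population-characteristics multiplier
(6 = 3 + 3), and so scores 17.9 × 6.0 ≈ 108 of a possible 120. `ciscreen
score` also writes `excluded.csv` (units missing an entire component,
with reason codes) and a `manifest.json` recording input digests and
warnings — here, that no statewide reference table was supplied, so
percentiles were computed over the 30 scored units themselves. Pass
`--reference statewide.csv` to rank against a larger pool. `ciscreen
check-redundancy --data sim/indicators.csv` reports pairwise Spearman
correlations to spot indicators that may duplicate information.

The same pipeline is available as a library: `read_config`,
`read_indicator_table`, `score_units`, `rank_units`, `top_contributors`,
`render_report`, and `generate_state` / `recovery_check` for synthetic
experiments.

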