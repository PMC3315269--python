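"""Unit tests for the scoring mathematics against hand-computed values."""

import math

import numpy as np
import pytest

from ciscreen import (
    ConfigurationError,
    IndicatorDefinition,
    IndicatorValueMatrix,
    InputDataError,
    ReferenceDistribution,
    ScoreCard,
    bin_score,
    component_score,
    cumulative_impact,
    percentile_rank,
    pollution_burden_score,
    population_characteristics_score,
    rank_units,
    score_units,
    top_contributors,
    indicator_redundancy,
)


def ref(*values):
    return ReferenceDistribution.from_values("x", values)


class TestPercentileRank:
    @pytest.mark.parametrize(
        "value, pool, expected",
        [
            (35, (10, 20, 30, 40, 50), 0.6),           # 3 below, none equal
            (1, tuple(range(1, 11)), 0.05),             # distinct minimum, n=10
            (7, (7,) * 10, 0.5),                        # all ties: symmetric mid-rank
            (100, tuple(range(1, 101)), 0.995),         # distinct maximum
            (0, (1, 2, 3), 1e-12),                      # below support clamps near 0
            (99, (1, 2, 3), 1.0),                       # above support clamps to 1
        ],
    )
    def test_mid_rank_rule(self, value, pool, expected):
        assert percentile_rank(value, ref(*pool)) == pytest.approx(expected)

    def test_strictly_increasing_over_support(self):
        pool = ref(3, 1, 4, 1, 5, 9, 2, 6)
        ranks = [percentile_rank(v, pool) for v in sorted(set(pool.sorted_values))]
        assert all(a < b for a, b in zip(ranks, ranks[1:]))

    def test_rejects_non_finite_value(self):
        with pytest.raises(InputDataError):
            percentile_rank(float("nan"), ref(1, 2, 3))

    def test_rejects_degenerate_reference(self):
        with pytest.raises(ConfigurationError):
            ReferenceDistribution.from_values("x", [1.0])


class TestBinScore:
    def test_extremes_of_a_distinct_reference(self):
        pool = ref(*range(1, 101))
        assert bin_score(100, pool, 10, True) == 10
        assert bin_score(1, pool, 10, True) == 1
        # beneficial direction reflects: best raw value scores least impact
        assert bin_score(100, pool, 10, False) == 1
        assert bin_score(1, pool, 10, False) == 10

    def test_full_tie_lands_mid_scale(self):
        assert bin_score(5, ref(5, 5, 5, 5), 10, True) == 5

    def test_decile_assignment_along_a_distinct_reference(self):
        pool = ref(*range(1, 101))
        scores = [bin_score(v, pool, 10, True) for v in range(1, 101)]
        # exactly ten units per decile when n divides evenly
        assert [scores.count(k) for k in range(1, 11)] == [10] * 10
        assert scores == sorted(scores)

    def test_rejects_single_bin(self):
        with pytest.raises(ConfigurationError):
            bin_score(1, ref(1, 2, 3), 1, True)


class TestAggregation:
    @pytest.mark.parametrize(
        "scores, expected",
        [([10], 10.0), ([4, 6], 5.0), ([3, None, 5], 4.0)],
    )
    def test_component_mean_skips_missing(self, scores, expected):
        assert component_score(scores) == expected

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            component_score([None, None])

    @pytest.mark.parametrize(
        "args, expected",
        [((1, 1, 1), 3.0), ((10, 5, 5), 20.0), ((7.5, 3, 2.5), 13.0)],
    )
    def test_pollution_burden_is_the_sum(self, args, expected):
        assert pollution_burden_score(*args) == expected

    @pytest.mark.parametrize(
        "args, expected", [((1, 1), 2.0), ((3, 3), 6.0), ((2, 2.5), 4.5)]
    )
    def test_population_characteristics_is_the_sum(self, args, expected):
        assert population_characteristics_score(*args) == expected

    @pytest.mark.parametrize(
        "burden, popchar, expected",
        [(3, 2, 6.0), (20, 6, 120.0), (16, 6, 96.0)],
    )
    def test_cumulative_impact_is_the_product(self, burden, popchar, expected):
        assert cumulative_impact(burden, popchar) == expected


class TestScoreUnits:
    def test_hand_traced_toy_problem(self, toy, specs):
        definitions, references, matrix = toy
        result = score_units(matrix, definitions, references, specs)
        by_id = {c.unit_id: c for c in result.cards}
        assert set(by_id) == {"X", "Y", "Z"}

        x = by_id["X"]
        assert x.indicator_scores == {"e1": 10, "h1": 3, "h2": 5, "v1": 1, "s1": 2, "o1": 3}
        assert x.component_scores == {
            "exposures": 10.0,
            "public_health_effects": 4.0,
            "environmental_effects": 1.0,
            "sensitive_populations": 2.0,
            "socioeconomic_factors": 3.0,
        }
        assert x.pollution_burden == 15.0
        assert x.population_characteristics == 5.0
        assert x.cumulative_impact == 75.0

        y = by_id["Y"]
        assert y.indicator_scores == {"e1": 1, "h1": 5, "h2": 1, "v1": 5, "s1": 1, "o1": 1}
        assert y.cumulative_impact == 18.0

        z = by_id["Z"]  # h1 missing: health component is the mean of h2 alone
        assert z.indicator_scores["h1"] is None
        assert z.component_scores["public_health_effects"] == 4.0
        assert z.cumulative_impact == 60.0

        for card in result.cards:
            card.check(specs)

    def test_unit_with_whole_component_missing_is_excluded(self, toy, specs):
        definitions, references, matrix = toy
        matrix.values[2, 1] = np.nan  # h1 already missing for Z
        matrix.values[2, 2] = np.nan  # now h2 too: no health data at all
        result = score_units(matrix, definitions, references, specs)
        assert {c.unit_id for c in result.cards} == {"X", "Y"}
        assert len(result.excluded) == 1
        assert result.excluded[0].unit_id == "Z"
        assert result.excluded[0].reason_code == "component_missing"
        assert "public_health_effects" in result.excluded[0].detail

    def test_missing_definition_or_reference_is_a_config_error(self, toy, specs):
        definitions, references, matrix = toy
        with pytest.raises(ConfigurationError) as exc:
            score_units(matrix, definitions[1:], references, specs)
        assert any("e1" in p for p in exc.value.problems)
        bad_refs = dict(references)
        del bad_refs["v1"]
        with pytest.raises(ConfigurationError) as exc:
            score_units(matrix, definitions, bad_refs, specs)
        assert any("v1" in p for p in exc.value.problems)

    def test_all_extreme_units_hit_the_bounds(self, specs):
        """A unit worst on everything scores 120; best on everything scores 6."""
        definitions = [
            IndicatorDefinition(id=f"i{c}", component=c) for c in specs
        ]
        references = {
            f"i{c}": ReferenceDistribution.from_values(f"i{c}", range(100)) for c in specs
        }
        matrix = IndicatorValueMatrix(
            unit_ids=["worst", "best"],
            indicator_ids=[d.id for d in definitions],
            values=np.array([[99.0] * 5, [0.0] * 5]),
        )
        cards = {c.unit_id: c for c in score_units(matrix, definitions, references, specs).cards}
        assert cards["worst"].cumulative_impact == 120.0
        assert cards["best"].cumulative_impact == 6.0


def make_card(uid, impact, comps=None):
    return ScoreCard(
        unit_id=uid,
        indicator_scores={},
        component_scores=comps or {},
        pollution_burden=0.0,
        population_characteristics=0.0,
        cumulative_impact=impact,
    )


class TestRankUnits:
    def test_orders_descending(self):
        ranked = rank_units([make_card("a", 96), make_card("b", 27), make_card("c", 50)])
        assert [(r, c.cumulative_impact) for r, c in ranked] == [(1, 96), (2, 50), (3, 27)]

    def test_full_tie_shares_rank_one_in_unit_order(self):
        ranked = rank_units([make_card(u, 42) for u in ("c", "a", "b")])
        assert [(r, c.unit_id) for r, c in ranked] == [(1, "a"), (1, "b"), (1, "c")]

    def test_min_rank_tie_convention(self):
        ranked = rank_units([make_card("a", 10), make_card("b", 10), make_card("c", 9)])
        assert [r for r, _ in ranked] == [1, 1, 3]

    def test_empty_input_rejected(self):
        with pytest.raises(InputDataError):
            rank_units([])


class TestTopContributors:
    def card_with(self, specs, **overrides):
        comps = {cid: float(s.min_score) for cid, s in specs.items()}
        comps.update(overrides)
        return make_card("u", 0.0, comps)

    def test_all_max_gives_unit_contributions_in_canonical_order(self, specs):
        card = self.card_with(specs, **{c: float(s.max_score) for c, s in specs.items()})
        out = top_contributors(card, specs)
        assert [v for _, v in out] == [1.0] * 5
        assert [c for c, _ in out] == list(card.component_scores)

    def test_single_maximal_component_leads(self, specs):
        out = top_contributors(self.card_with(specs, exposures=10.0), specs)
        assert out[0] == ("exposures", 1.0)
        assert all(v == 0.0 for _, v in out[1:])

    def test_normalization_makes_ranges_comparable(self, specs):
        # exposures halfway up a 1-10 range loses to a maxed 1-3 component
        out = top_contributors(
            self.card_with(specs, exposures=5.5, sensitive_populations=3.0), specs
        )
        assert out[0] == ("sensitive_populations", 1.0)
        assert out[1][0] == "exposures"
        assert out[1][1] == pytest.approx(0.5)


class TestIndicatorRedundancy:
    def test_duplicated_and_reversed_columns_are_flagged(self):
        rng = np.random.default_rng(7)
        a = rng.random(50)
        matrix = IndicatorValueMatrix(
            unit_ids=[f"u{i}" for i in range(50)],
            indicator_ids=["a", "a_copy", "a_flip"],
            values=np.column_stack([a, a, 1.0 / (1.0 + a)]),
        )
        pairs = {(p.indicator_a, p.indicator_b): p for p in indicator_redundancy(matrix, 0.8)}
        assert pairs[("a", "a_copy")].rho == pytest.approx(1.0)
        assert pairs[("a", "a_copy")].flagged
        assert pairs[("a", "a_flip")].rho == pytest.approx(-1.0)
        assert pairs[("a", "a_flip")].flagged

    def test_independent_columns_not_flagged_at_n_1000(self):
        rng = np.random.default_rng(11)
        matrix = IndicatorValueMatrix(
            unit_ids=[f"u{i}" for i in range(1000)],
            indicator_ids=["a", "b"],
            values=rng.random((1000, 2)),
        )
        (pair,) = indicator_redundancy(matrix, 0.8)
        assert pair.evaluable and not pair.flagged
        assert abs(pair.rho) < 0.2

    def test_insufficient_pairs_reported_not_raised(self):
        matrix = IndicatorValueMatrix(
            unit_ids=["u1", "u2", "u3"],
            indicator_ids=["a", "b"],
            values=np.array([[1.0, np.nan], [2.0, 1.0], [3.0, 2.0]]),
        )
        (pair,) = indicator_redundancy(matrix, 0.8)
        assert not pair.evaluable and pair.n_pairs == 2 and not pair.flagged
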