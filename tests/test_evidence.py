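"""Evidence scoring, Agresti-Coull intervals and prevalent-hypothesis rule."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttdrank import (
    Direction,
    ModelTier,
    SummaryConfig,
    agresti_coull_interval,
    build_predictor_set,
    determine_prevalent,
    minimal_base_score,
    model_score,
    record_weight,
    score_percentages,
    size_score,
    summarize_corpus,
    tally_group,
    z_test_proportion,
)
from ttdrank.evidence import DIRECTIONS, HypothesisTally

from conftest import make_record

CFG = SummaryConfig()
ADDITIVE = SummaryConfig(size_combination="additive")


def tally(es_pos, es_neg, es_null):
    return HypothesisTally(
        es={
            Direction.POSITIVE: float(es_pos),
            Direction.NEGATIVE: float(es_neg),
            Direction.NULL: float(es_null),
        },
        n_records={d: 1 for d in DIRECTIONS},
    )


class TestScores:
    @pytest.mark.parametrize(
        "tier,expected",
        [
            (ModelTier.ANIMAL_IN_VITRO, 6),
            (ModelTier.ANIMAL_IN_VIVO, 12),
            (ModelTier.HUMAN_IN_VITRO, 24),
            (ModelTier.HUMAN_XENOGRAFT, 48),
            (ModelTier.CLINICAL_STUDY, 96),
            (ModelTier.RANDOMIZED_CONTROLLED_TRIAL, 192),
            (ModelTier.META_ANALYSIS, 384),
        ],
    )
    def test_model_score_ladder(self, tier, expected):
        assert model_score(tier, CFG) == expected

    def test_adjacent_tiers_exactly_double(self):
        for lo, hi in zip(list(ModelTier)[:-1], list(ModelTier)[1:]):
            assert model_score(hi, CFG) == 2 * model_score(lo, CFG)

    @pytest.mark.parametrize("cases,expected", [(None, 0.0), (100, 10.0), (7, 0.7)])
    def test_size_score(self, cases, expected):
        assert size_score(cases) == expected

    def test_negative_cases_rejected(self):
        with pytest.raises(ValueError):
            size_score(-1)

    def test_record_weight_multiplicative(self):
        rec = make_record(model=ModelTier.RANDOMIZED_CONTROLLED_TRIAL, cases=200)
        assert record_weight(rec, CFG) == 192 * 21  # 4032

    def test_record_weight_additive(self):
        rec = make_record(model=ModelTier.CLINICAL_STUDY, cases=10)
        assert record_weight(rec, ADDITIVE) == 96 + 1

    def test_record_weight_without_cases_is_tier_score(self):
        rec = make_record(model=ModelTier.ANIMAL_IN_VITRO)
        assert record_weight(rec, CFG) == record_weight(rec, ADDITIVE) == 6


class TestTallyAndPercentages:
    def test_tally_sums_weights_per_direction(self):
        records = [
            make_record(1, hypothesis=1),
            make_record(2, hypothesis=1),
            make_record(3, hypothesis=-1),
        ]
        t = tally_group(records, CFG)
        assert t.es[Direction.POSITIVE] == 12
        assert t.es[Direction.NEGATIVE] == 6
        assert t.es[Direction.NULL] == 0

    def test_mixed_tiers(self):
        records = [
            make_record(1, hypothesis=1, model=ModelTier.RANDOMIZED_CONTROLLED_TRIAL),
            make_record(2, hypothesis=-1, model=ModelTier.ANIMAL_IN_VITRO),
        ]
        t = tally_group(records, CFG)
        assert (t.es[Direction.POSITIVE], t.es[Direction.NEGATIVE]) == (192, 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            tally_group([], CFG)

    @pytest.mark.parametrize(
        "es,expected",
        [((70, 20, 10), (0.7, 0.2, 0.1)), ((6, 0, 0), (1, 0, 0)), ((5, 5, 0), (0.5, 0.5, 0))],
    )
    def test_score_percentages(self, es, expected):
        sps = score_percentages(tally(*es))
        assert [sps[d] for d in DIRECTIONS] == pytest.approx(list(expected))

    def test_zero_total_raises(self):
        with pytest.raises(ValueError, match="undetermined"):
            score_percentages(tally(0, 0, 0))

    @given(
        st.tuples(
            st.floats(0, 1e4), st.floats(0, 1e4), st.floats(0, 1e4)
        ).filter(lambda t: sum(t) > 1e-6)
    )
    def test_percentages_sum_to_one(self, es):
        assert sum(score_percentages(tally(*es)).values()) == pytest.approx(1, abs=1e-12)


class TestAgrestiCoull:
    def test_single_base6_study_interval(self):
        # frozen from the closed-form AC computation with z = 1.959964
        est = agresti_coull_interval(6, 6, 0.95)
        assert est.sp_corrected == pytest.approx(0.8048328560, abs=1e-9)
        assert est.se == pytest.approx(0.1263358080, abs=1e-9)
        assert est.ci_low == pytest.approx(0.5572192224, abs=1e-9)
        assert est.ci_high == 1.0  # clipped

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            agresti_coull_interval(0, 0)

    def test_es_above_total_rejected(self):
        with pytest.raises(ValueError):
            agresti_coull_interval(7, 6)

    def test_half_total_gives_exactly_half(self):
        est = agresti_coull_interval(21.5, 43.0)
        assert est.sp_corrected == pytest.approx(0.5, abs=1e-15)

    def test_matches_statsmodels_on_integer_grid(self):
        from statsmodels.stats.proportion import proportion_confint

        for n in range(1, 51):
            for x in range(0, n + 1):
                lo, hi = proportion_confint(x, n, alpha=0.05, method="agresti_coull")
                est = agresti_coull_interval(float(x), float(n))
                assert est.ci_low == pytest.approx(max(0.0, lo), abs=1e-9)
                assert est.ci_high == pytest.approx(min(1.0, hi), abs=1e-9)


class TestZTest:
    def test_against_frozen_normal_cdf_values(self):
        est = agresti_coull_interval(6, 6, 0.95)
        z, p = z_test_proportion(est, 0.5)
        assert z == pytest.approx(2.4128777, abs=1e-6)
        assert p == pytest.approx(0.0158271, abs=1e-6)

    def test_at_threshold_z_zero_p_one(self):
        est = agresti_coull_interval(21.5, 43.0)
        z, p = z_test_proportion(est, 0.5)
        assert z == pytest.approx(0) and p == pytest.approx(1)

    def test_mirror_symmetry(self):
        lo = agresti_coull_interval(10, 40)
        hi = agresti_coull_interval(30, 40)
        z1, p1 = z_test_proportion(lo, 0.5)
        z2, p2 = z_test_proportion(hi, 0.5)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)


class TestPrevalent:
    def test_single_base6_record_is_prevalent_positive(self):
        summary = determine_prevalent(tally(6, 0, 0), CFG)
        assert summary.prevalent == "positive"

    def test_even_split_undetermined(self):
        assert determine_prevalent(tally(50, 50, 0), CFG).prevalent == "undetermined"

    def test_seventy_percent_needs_tight_interval(self):
        # SP = 0.7 on both sides of the CI boundary: small total fails,
        # large total passes
        assert determine_prevalent(tally(14, 6, 0), CFG).prevalent == "undetermined"
        assert determine_prevalent(tally(42, 18, 0), CFG).prevalent == "positive"

    def test_zero_total_flagged_undetermined(self):
        summary = determine_prevalent(tally(0, 0, 0), CFG)
        assert summary.prevalent == "undetermined" and summary.flags

    def test_tie_at_threshold_fails_strict_rule(self):
        assert determine_prevalent(tally(500, 500, 0), CFG).prevalent == "undetermined"

    def test_z_test_criterion_also_qualifies_single_study(self):
        cfg = SummaryConfig(criterion="z_test")
        assert determine_prevalent(tally(6, 0, 0), cfg).prevalent == "positive"

    @given(
        st.tuples(st.floats(0, 1e3), st.floats(0, 1e3), st.floats(0, 1e3)).filter(
            lambda t: sum(t) > 1e-3
        )
    )
    @settings(max_examples=200)
    def test_at_most_one_direction_qualifies(self, es):
        summary = determine_prevalent(tally(*es), CFG)
        assert "multiple qualifying directions" not in summary.flags

    @given(st.integers(0, 6), st.floats(1, 500), st.floats(1, 500))
    @settings(max_examples=100)
    def test_supporting_record_never_decreases_own_sp(self, tier, es_pos, es_neg):
        base = tally(es_pos, es_neg, 0)
        sps_before = score_percentages(base)
        add = model_score(ModelTier(tier), CFG)
        grown = tally(es_pos + add, es_neg, 0)
        sps_after = score_percentages(grown)
        assert sps_after[Direction.POSITIVE] >= sps_before[Direction.POSITIVE]
        assert sps_after[Direction.NEGATIVE] <= sps_before[Direction.NEGATIVE]


class TestSummarizeCorpus:
    def test_distinct_pairs_give_distinct_groups(self, small_table):
        summaries = summarize_corpus(small_table, CFG)
        assert len(summaries) == 2
        assert {s.key.drug for s in summaries} == {"sorafenib", "imatinib"}

    def test_states_split_groups(self):
        records = [
            make_record(1, state="mut V600E", hypothesis=1),
            make_record(2, state="wt", hypothesis=-1),
        ]
        assert len(summarize_corpus(records, CFG)) == 2

    def test_row_order_invariance(self, corpus):
        forward = summarize_corpus(corpus, CFG)
        backward = summarize_corpus(list(reversed(corpus)), CFG)
        assert [s.key for s in forward] == [s.key for s in backward]
        assert [s.prevalent for s in forward] == [s.prevalent for s in backward]

    def test_appending_records_equals_from_scratch(self, small_table):
        extra = make_record(99, hypothesis=-1, model=ModelTier.META_ANALYSIS)
        incremental = summarize_corpus(small_table + [extra], CFG)
        scratch = summarize_corpus([extra] + small_table, CFG)
        assert [s.prevalent for s in incremental] == [s.prevalent for s in scratch]

    def test_alias_map_merges_synonyms(self):
        records = [
            make_record(1, molecule="BRAF", hypothesis=1),
            make_record(2, molecule="B-raf", hypothesis=1),
        ]
        merged = summarize_corpus(records, CFG, alias_map={"b-raf": "braf"})
        assert len(merged) == 1

    def test_case_and_whitespace_normalization_groups_together(self):
        records = [
            make_record(1, molecule="BRAF", drug="Sorafenib"),
            make_record(2, molecule="braf ", drug="  sorafenib"),
        ]
        assert len(summarize_corpus(records, CFG)) == 1


class TestPredictorSet:
    def test_null_and_undetermined_groups_excluded(self):
        records = [
            # strong positive group
            make_record(1, molecule="A", hypothesis=1, model=ModelTier.META_ANALYSIS),
            # strong null group -> eliminated
            make_record(2, molecule="B", hypothesis=0, model=ModelTier.META_ANALYSIS),
            # conflicted group -> undetermined
            make_record(3, molecule="C", hypothesis=1),
            make_record(4, molecule="C", hypothesis=-1),
        ]
        summaries = summarize_corpus(records, CFG)
        preds = build_predictor_set(summaries, "sorafenib")
        assert [p.molecule for p in preds] == ["a"]
        assert preds[0].direction is Direction.POSITIVE

    def test_empty_summaries_give_empty_set(self):
        assert build_predictor_set([], "anything") == []


class TestMinimalBaseScore:
    def test_ci_rule_minimum_qualifies_and_below_fails(self):
        b = minimal_base_score(criterion="ci_lower_bound")
        assert determine_prevalent(
            tally(b, 0, 0), SummaryConfig(base_score=b)
        ).prevalent == "positive"
        assert determine_prevalent(
            tally(b - 1, 0, 0), SummaryConfig(base_score=max(b - 1, 1))
        ).prevalent == "undetermined"

    def test_monotone_in_threshold(self):
        assert minimal_base_score(threshold=0.99) > minimal_base_score(threshold=0.5)

    def test_null_se_z_test_differs_from_ci_rule(self):
        assert minimal_base_score(criterion="z_test_null") > minimal_base_score(
            criterion="ci_lower_bound"
        )
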