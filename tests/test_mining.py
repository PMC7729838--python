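"""Apriori mining, rule metrics, oracle equivalence, dedup and summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comopat import (
    MiningThresholds,
    TransactionDB,
    apriori_frequent_itemsets,
    brute_force_itemsets,
    brute_force_rules,
    dedupe_by_itemset,
    generate_rules,
    mine_rules,
    rule_metrics,
    summarize_rules,
)
from comopat.mining import MetricUndefinedError
from comopat.reference import published_rules


def _rule_keys(rules):
    return {(tuple(sorted(r.lhs)), r.rhs, round(r.support, 12), round(r.confidence, 12),
             round(r.lift, 12)) for r in rules}


class TestRuleMetrics:
    def test_hand_enumerated_four_transactions(self, pair_tdb):
        sup, conf, lift = rule_metrics(pair_tdb, {"A"}, "B")
        assert sup == pytest.approx(0.5, abs=1e-15)
        assert conf == pytest.approx(2 / 3, abs=1e-15)
        assert lift == pytest.approx(8 / 9, abs=1e-15)

    def test_ubiquitous_consequent_lift_equals_confidence(self):
        tdb = TransactionDB.from_sets([{"X", "Y"}, {"Y"}, {"X", "Y"}])
        _, conf, lift = rule_metrics(tdb, {"X"}, "Y")
        assert lift == conf == 1.0  # P(Y) = 1 limit

    def test_absent_lhs_raises(self):
        tdb = TransactionDB.from_sets([{"B"}])
        with pytest.raises(MetricUndefinedError):
            rule_metrics(tdb, {"A"}, "B")

    def test_independent_planted_pair_lift_near_one(self):
        from comopat import CohortConfig, build_transactions, filter_cohort, generate_cohort
        from comopat.synthetic import catalog_for

        cfg = CohortConfig(n_patients=20000, disease_marginals={"X": 0.2, "Y": 0.5},
                           rng_seed=23)
        cat = catalog_for(cfg)
        kept, _ = filter_cohort(generate_cohort(cfg), cat)
        _, _, lift = rule_metrics(build_transactions(kept, cat), {"X"}, "Y")
        # delta-method SE of lift under independence at p_x=.2, p_y=.5
        se = (1 / 0.2 / 0.5 / 20000 * (1 - 0.2) * (1 - 0.5)) ** 0.5
        assert abs(lift - 1.0) <= 3 * se


class TestApriori:
    def test_min_support_above_max_frequency_empty(self, toy_tdb):
        assert apriori_frequent_itemsets(toy_tdb, min_support=0.99) == []

    def test_matches_exhaustive_enumeration_on_toy(self, toy_tdb):
        a = apriori_frequent_itemsets(toy_tdb, min_support=0.3, max_itemset_size=3)
        b = brute_force_itemsets(toy_tdb, min_support=0.3, max_itemset_size=3)
        assert [(s.items, s.count) for s in a] == [(s.items, s.count) for s in b]

    def test_anti_monotone_support(self, toy_tdb):
        itemsets = apriori_frequent_itemsets(toy_tdb, min_support=0.0, max_itemset_size=3)
        support = {s.items: s.support for s in itemsets}
        for items, sup in support.items():
            for item in items:
                if len(items) > 1:
                    assert support[items - {item}] >= sup

    def test_strict_threshold(self):
        # item in exactly 1 of 4 transactions: support 0.25 is NOT > 0.25
        tdb = TransactionDB.from_sets([{"A"}, set(), set(), set()])
        assert apriori_frequent_itemsets(tdb, min_support=0.25) == []
        assert len(apriori_frequent_itemsets(tdb, min_support=0.24)) == 1


class TestGenerateRules:
    def test_perfectly_correlated_pair(self):
        tdb = TransactionDB.from_sets([{"A", "B"}] * 3 + [set()] * 7)
        rules = mine_rules(tdb, MiningThresholds(0.1, 0.5, 1.0, 2))
        keys = {(tuple(sorted(r.lhs)), r.rhs) for r in rules}
        assert keys == {(("A",), "B"), (("B",), "A")}
        for r in rules:
            assert r.confidence == 1.0
            assert r.lift == pytest.approx(1 / 0.3, abs=1e-12)

    def test_toy_set_equals_brute_force(self, toy_tdb):
        th = MiningThresholds(0.1, 0.4, 0.7, 3)
        mined = generate_rules(apriori_frequent_itemsets(toy_tdb, 0.1, 3), toy_tdb, th)
        assert _rule_keys(mined) == _rule_keys(brute_force_rules(toy_tdb, th))
        assert mined  # the toy set does produce rules at these thresholds

    def test_metric_identities(self, toy_tdb):
        n = toy_tdb.n_patients
        for r in mine_rules(toy_tdb, MiningThresholds(0.0, 0.0, 0.0, 3)):
            assert abs(r.lift * (r.count_rhs / n) - r.confidence) < 1e-12
            assert abs(r.confidence * (r.count_lhs / n) - r.support) < 1e-12

    def test_threshold_monotonicity(self, toy_tdb):
        base = _rule_keys(mine_rules(toy_tdb, MiningThresholds(0.05, 0.2, 0.5, 3)))
        for tighter in [MiningThresholds(0.2, 0.2, 0.5, 3),
                        MiningThresholds(0.05, 0.6, 0.5, 3),
                        MiningThresholds(0.05, 0.2, 1.2, 3)]:
            assert _rule_keys(mine_rules(toy_tdb, tighter)) <= base


@st.composite
def transaction_sets(draw):
    n_items = draw(st.integers(2, 8))
    items = [f"I{i}" for i in range(n_items)]
    n_trans = draw(st.integers(1, 30))
    sets = [draw(st.sets(st.sampled_from(items), max_size=n_items)) for _ in range(n_trans)]
    return TransactionDB.from_sets(sets)


class TestOracleEquivalence:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(tdb=transaction_sets(),
           min_support=st.floats(0.0, 0.4),
           min_confidence=st.floats(0.0, 0.9),
           min_lift=st.floats(0.0, 2.0),
           max_size=st.integers(2, 4))
    def test_apriori_rules_equal_brute_force(self, tdb, min_support, min_confidence,
                                             min_lift, max_size):
        th = MiningThresholds(min_support, min_confidence, min_lift, max_size)
        assert _rule_keys(mine_rules(tdb, th)) == _rule_keys(brute_force_rules(tdb, th))

    def test_brute_force_degenerate_inputs(self):
        assert brute_force_rules(TransactionDB.from_sets([])) == []
        assert brute_force_rules(TransactionDB.from_sets([{"A"}])) == []

    def test_brute_force_item_guard(self):
        tdb = TransactionDB.from_sets([{f"I{i}"} for i in range(21)])
        with pytest.raises(ValueError, match="guard"):
            brute_force_rules(tdb)


class TestDedupe:
    def test_published_fixture_groups_to_30_and_keeps_highest_confidence(self):
        rules = published_rules()
        result = dedupe_by_itemset(rules)
        assert result.n_groups == 30
        assert len(result.kept) == 30
        assert len(result.dropped) == 11
        triple = frozenset({"Atherosclerotic heart disease", "Ischemic cardiomyopathy",
                            "Heart failure"})
        winner = [r for r in result.kept if r.itemset == triple]
        assert len(winner) == 1 and winner[0].confidence == 0.92

    def test_distinct_itemsets_pass_through(self, toy_tdb):
        rules = mine_rules(toy_tdb, MiningThresholds(0.1, 0.5, 1.0, 2))
        by_itemset = {}
        distinct = [by_itemset.setdefault(r.itemset, r) for r in rules]
        distinct = list(dict.fromkeys(distinct))
        assert dedupe_by_itemset(distinct).kept == distinct


class TestSummarize:
    def test_published_fixture_summary(self):
        s = summarize_rules(published_rules())
        assert s.lift_max == 8.58
        assert round(s.lift_mean, 2) == 4.91
        assert (s.confidence_min, s.confidence_max) == (0.50, 0.92)
        assert s.support_max == 0.06

    def test_single_rule_min_equals_max_equals_mean(self):
        [s] = [summarize_rules(published_rules()[:1])]
        assert s.lift_min == s.lift_max == s.lift_mean

    def test_empty_summary_marker(self):
        s = summarize_rules([])
        assert s.empty and s.as_dict()["lift_mean"] is None
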