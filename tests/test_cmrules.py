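import math

import pytest

from seqrules.cmrules import (SequentialRuleMiner, filter_very_strong,
                              generate_candidate_rules, match_rules,
                              mine_contrast, mine_frequent_itemsets,
                              mine_sequential_rules, sequence_contains)
from seqrules.data_model import RuleSet
from seqrules.metrics import rule_metrics
from seqrules.seqdb import SequenceDatabase

from _oracles import bf_frequent_itemsets, bf_mine_rules, random_database
from conftest import A_UP, B_DOWN, C_UP, D_DOWN, make_rule


def _codes(rule):
    return (frozenset(int(i.probe) for i in rule.lhs),
            frozenset(int(i.probe) for i in rule.rhs))


class TestFrequentItemsets:
    def test_db_plus_at_half_support(self, db_plus):
        found = {fi.items: fi.count
                 for fi in mine_frequent_itemsets(db_plus, 0.5)}
        assert found == {
            frozenset({A_UP}): 3,
            frozenset({B_DOWN}): 3,
            frozenset({A_UP, B_DOWN}): 3,
        }

    def test_full_support_threshold_empty(self, db_plus):
        assert mine_frequent_itemsets(db_plus, 1.0) == []

    def test_matches_powerset_oracle(self, rng):
        for _ in range(30):
            sequences = random_database(rng)
            db = SequenceDatabase(group="r", sequences=sequences)
            min_sup = float(rng.choice([0.2, 0.4, 0.6]))
            mined = {fi.items: fi.count
                     for fi in mine_frequent_itemsets(db, min_sup,
                                                      max_size=None)}
            assert mined == bf_frequent_itemsets(sequences, min_sup)

    def test_empty_database(self):
        db = SequenceDatabase(group="g", sequences=[])
        with pytest.raises(ValueError, match="empty"):
            mine_frequent_itemsets(db, 0.5)


class TestCandidateRules:
    def test_perfect_confidence_candidate(self, db_plus):
        frequent = mine_frequent_itemsets(db_plus, 0.5)
        candidates = generate_candidate_rules(frequent, min_conf=1.0)
        assert (frozenset({A_UP}), frozenset({B_DOWN})) in candidates

    def test_unreachable_confidence(self, db_plus):
        frequent = mine_frequent_itemsets(db_plus, 0.5)
        assert generate_candidate_rules(frequent, min_conf=1.01) == []


class TestSequenceContains:
    def test_simple_order(self):
        assert sequence_contains([{1}, {2}], {1}, {2})

    def test_single_itemset_never_contains(self):
        # no cut point exists inside one itemset
        assert not sequence_contains([{1, 2}], {1}, {2})

    def test_lhs_items_may_straddle_itemsets(self):
        assert sequence_contains([{1}, {3}, {2}], {1, 3}, {2})

    def test_reversed_order_rejected(self):
        assert not sequence_contains([{2}, {1}], {1}, {2})


class TestRuleMetrics:
    def test_db_plus_hand_computation(self):
        m = rule_metrics(3, 3, 3, 4)
        assert m.seq_sup == pytest.approx(0.75)
        assert m.seq_conf == pytest.approx(1.0)
        assert m.lift == pytest.approx(4 / 3)
        assert m.cf == pytest.approx(1.0)
        assert math.isinf(m.conviction)

    def test_db_minus_hand_computation(self):
        m = rule_metrics(2, 3, 4, 4)
        assert m.seq_sup == pytest.approx(0.5)
        assert m.seq_conf == pytest.approx(2 / 3)
        assert m.lift == pytest.approx(2 / 3)
        assert m.cf == pytest.approx(-1 / 3)
        assert m.conviction == pytest.approx(0.0)

    def test_independence(self):
        # sup_seq = sup_lhs * sup_rhs / n -> lift 1, cf 0
        m = rule_metrics(2, 4, 4, 8)
        assert m.lift == pytest.approx(1.0)
        assert m.cf == 0.0

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError, match="inconsistent"):
            rule_metrics(5, 3, 3, 4)
        with pytest.raises(ValueError, match="sup_lhs = 0"):
            rule_metrics(0, 0, 3, 4)


class TestMineSequentialRules:
    def test_db_plus_single_rule(self, db_plus):
        rules = mine_sequential_rules(db_plus, 0.5, 0.5)
        assert len(rules) == 1
        rule = rules.rules[0]
        assert _codes(rule) == (frozenset({A_UP}), frozenset({B_DOWN}))
        assert (rule.sup_seq, rule.sup_lhs, rule.sup_rhs) == (3, 3, 3)
        assert rule.n_neither == 1

    def test_single_sequence_db(self):
        db = SequenceDatabase(group="g", sequences=[
            [frozenset({2001}), frozenset({1002})]])
        rules = mine_sequential_rules(db, 1.0, 1.0)
        assert len(rules) == 1
        assert rules.rules[0].seq_sup == 1.0
        assert rules.rules[0].seq_conf == 1.0

    def test_threshold_monotonicity(self, db_plus, db_minus):
        for db in (db_plus, db_minus):
            loose = {r.key() for r in mine_sequential_rules(db, 0.45, 0.4)}
            tight = {r.key() for r in mine_sequential_rules(db, 0.5, 0.6)}
            assert tight <= loose

    def test_oracle_equivalence_quick(self, rng):
        """Mined rules and every count match brute-force enumeration."""
        for _ in range(40):
            sequences = random_database(rng)
            db = SequenceDatabase(group="r", sequences=sequences)
            min_sup = float(rng.choice([0.2, 0.4, 0.5]))
            min_conf = float(rng.choice([0.4, 0.6, 0.8]))
            mined = mine_sequential_rules(db, min_sup, min_conf,
                                          max_itemset_size=None)
            got = {_codes(r): (r.sup_seq, r.sup_lhs, r.sup_rhs, r.n_neither)
                   for r in mined}
            assert got == bf_mine_rules(sequences, min_sup, min_conf)

    def test_estimator_api(self, db_plus):
        miner = SequentialRuleMiner(min_seq_sup=0.5, min_seq_conf=0.5)
        params = miner.get_params()
        assert params["min_seq_sup"] == 0.5
        clone = SequentialRuleMiner(**params).fit(db_plus)
        assert len(clone.rules_) == 1
        assert clone.n_sequences_ == 4

    def test_invalid_thresholds(self, db_plus):
        with pytest.raises(ValueError, match="thresholds"):
            SequentialRuleMiner(min_seq_sup=0.0).fit(db_plus)

    def test_deterministic_ordering(self, db_minus):
        r1 = mine_sequential_rules(db_minus, 0.25, 0.25)
        r2 = mine_sequential_rules(db_minus, 0.25, 0.25)
        assert [r.key() for r in r1] == [r.key() for r in r2]
        confs = [r.seq_conf for r in r1]
        assert confs == sorted(confs, reverse=True)


class TestVeryStrong:
    def test_cf_only_keeps_positive_dependence(self, db_plus):
        rules = mine_sequential_rules(db_plus, 0.45, 0.4)
        kept = filter_very_strong(rules, 0.45, variant="cf_only")
        assert [_codes(r) for r in kept] == [
            (frozenset({A_UP}), frozenset({B_DOWN}))]

    def test_literal_variant_requires_counter_reciprocal_support(self, db_plus):
        rules = mine_sequential_rules(db_plus, 0.45, 0.4)
        kept = filter_very_strong(rules, 0.45, variant="literal")
        # notsup_frac = 1/4 <= 1 - 0.45 -> dropped
        assert len(kept) == 0

    def test_counter_reciprocal_variant(self, db_plus):
        rules = mine_sequential_rules(db_plus, 0.45, 0.4)
        kept = filter_very_strong(rules, 0.45, variant="counter_reciprocal",
                                  not_sup_threshold=0.2)
        assert len(kept) == 1
        with pytest.raises(ValueError, match="not_sup_threshold"):
            filter_very_strong(rules, 0.45, variant="counter_reciprocal")

    def test_negative_cf_dropped_under_every_variant(self):
        rule = make_rule([("2001", 2, None)], [("1002", 1, None)],
                         2, 3, 4, 4, n_neither=0)
        assert rule.cf < 0
        rs = RuleSet("g", [rule])
        for variant in ("cf_only", "literal"):
            assert len(filter_very_strong(rs, 0.1, variant=variant)) == 0

    def test_unknown_variant(self, db_plus):
        rules = mine_sequential_rules(db_plus, 0.45, 0.4)
        with pytest.raises(ValueError, match="variant"):
            filter_very_strong(rules, 0.45, variant="bogus")


class TestContrast:
    def test_exclusive_rules_split(self, db_plus):
        # B carries the same A->B pattern in only 1 of 4 sequences
        db_b = SequenceDatabase(group="b", sequences=[
            [frozenset({A_UP}), frozenset({B_DOWN})],
            [frozenset({C_UP}), frozenset({D_DOWN})],
            [frozenset({C_UP}), frozenset({D_DOWN})],
            [frozenset({C_UP}), frozenset({D_DOWN})],
        ])
        only_a, only_b = mine_contrast(db_plus, db_b, 0.5, 0.5)
        a_keys = {_codes(r) for r in only_a}
        b_keys = {_codes(r) for r in only_b}
        assert (frozenset({A_UP}), frozenset({B_DOWN})) in a_keys
        assert (frozenset({C_UP}), frozenset({D_DOWN})) in b_keys
        assert a_keys.isdisjoint(b_keys)

    def test_rule_passing_in_both_absent_from_both(self, db_plus):
        only_a, only_b = mine_contrast(db_plus, db_plus, 0.5, 0.5)
        assert len(only_a) == 0 and len(only_b) == 0


class TestMatchRules:
    def test_same_genes_different_probes_replicate(self):
        r1 = make_rule([("p101", 2, "G1")], [("p202", 1, "G2")], 3, 3, 3, 4)
        r2 = make_rule([("p999", 2, "G1")], [("p555", 1, "G2")], 2, 2, 2, 4)
        groups = match_rules([RuleSet("d1", [r1]), RuleSet("d2", [r2])])
        assert len(groups) == 1
        assert {label for label, _ in groups[0]} == {"d1", "d2"}

    def test_state_mismatch_requires_ignore_state(self):
        r_down = make_rule([("p1", 1, "G1")], [("p2", 1, "G2")], 3, 3, 3, 4)
        r_up = make_rule([("p9", 2, "G1")], [("p8", 2, "G2")], 3, 3, 3, 4)
        sets = [RuleSet("d1", [r_down]), RuleSet("d2", [r_up])]
        assert match_rules(sets) == []
        assert len(match_rules(sets, ignore_state=True)) == 1

    def test_single_dataset_is_error(self):
        r = make_rule([("p1", 1, "G1")], [("p2", 1, "G2")], 3, 3, 3, 4)
        with pytest.raises(ValueError, match=">= 2"):
            match_rules([RuleSet("d1", [r])])

    def test_within_dataset_duplicates_do_not_replicate(self):
        r1 = make_rule([("p1", 1, "G1")], [("p2", 1, "G2")], 3, 3, 3, 4)
        r2 = make_rule([("p9", 1, "G1")], [("p8", 1, "G2")], 3, 3, 3, 4)
        sets = [RuleSet("d1", [r1, r2]), RuleSet("d2", [])]
        assert match_rules(sets) == []


class TestPruningSoundness:
    def test_sequential_bounded_by_association(self, rng):
        """seq_sup <= flattened association support and seq_conf <=
        association confidence on every rule of random databases."""
        for _ in range(20):
            sequences = random_database(rng)
            db = SequenceDatabase(group="r", sequences=sequences)
            flats = [frozenset().union(*s) if s else frozenset()
                     for s in sequences]
            n = len(sequences)
            mined = mine_sequential_rules(db, 0.2, 0.2,
                                          max_itemset_size=None)
            for rule in mined:
                lhs, rhs = _codes(rule)
                assoc_joint = sum(1 for t in flats if lhs | rhs <= t)
                assoc_lhs = sum(1 for t in flats if lhs <= t)
                assert rule.sup_seq <= assoc_joint
                assert rule.seq_sup <= assoc_joint / n + 1e-12
                assert rule.seq_conf <= assoc_joint / assoc_lhs + 1e-12
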