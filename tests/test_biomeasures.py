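import itertools

import pytest

from seqrules.biomeasures import (BiologicalScorer, assign_category,
                                  compute_points, find_matches,
                                  read_match_report, score_ruleset, tf_score,
                                  write_match_report)
from seqrules.data_model import AnnotationTable, RuleSet, TFTable

from conftest import make_rule


def _annotation(mapping, namespace="BP"):
    table = AnnotationTable(namespace=namespace)
    for gene, terms in mapping.items():
        for term in terms:
            table.add(gene, term)
    return table


class TestFindMatches:
    def test_shared_term_full_coverage(self):
        rule = make_rule([("p1", 2, "G1")], [("p2", 1, "G2")], 3, 3, 3, 4)
        ann = _annotation({"G1": {"T1", "T2"}, "G2": {"T1"}})
        ms = find_matches(rule, ann)
        assert ms.matches == [("T1", frozenset({"G1", "G2"}))]
        assert ms.f_best == 1.0

    def test_partial_coverage(self):
        rule = make_rule([("p1", 2, "G1"), ("p3", 2, "G3")],
                         [("p2", 1, "G2")], 3, 3, 3, 4)
        ann = _annotation({"G1": {"T1"}, "G2": {"T1"}, "G3": {"T3"}})
        ms = find_matches(rule, ann)
        assert ms.matches == [("T1", frozenset({"G1", "G2"}))]
        assert ms.f_best == pytest.approx(2 / 3)

    def test_disjoint_annotations_empty(self):
        rule = make_rule([("p3", 2, "G3")], [("p4", 1, "G4")], 3, 3, 3, 4)
        ann = _annotation({"G3": {"T3"}, "G4": {"T4"}})
        ms = find_matches(rule, ann)
        assert ms.matches == [] and ms.f_best is None

    def test_same_side_terms_are_not_cross_matches(self):
        rule = make_rule([("p1", 2, "G1"), ("p3", 2, "G3")],
                         [("p2", 1, "G2")], 3, 3, 3, 4)
        ann = _annotation({"G1": {"TL"}, "G3": {"TL"}, "G2": {"TR"}})
        assert find_matches(rule, ann).matches == []

    def test_two_probes_one_gene_deduplicated(self):
        rule = make_rule([("p1", 2, "G1"), ("p9", 1, "G1")],
                         [("p2", 1, "G2")], 3, 3, 3, 4)
        ann = _annotation({"G1": {"T1"}, "G2": {"T1"}})
        ms = find_matches(rule, ann)
        assert ms.n_rule_genes == 2
        assert ms.f_best == 1.0


class TestCategoriesAndPoints:
    @pytest.mark.parametrize("n_covered,denom,expected", [
        (12, 12, 1),   # f_best = 1
        (8, 10, 2),    # 0.8
        (9, 12, 2),    # 0.75 inclusive
        (8, 12, 3),    # 2/3
        (6, 12, 3),    # 0.5 inclusive
        (4, 10, 4),    # any cross match below 0.5
    ])
    def test_bands(self, n_covered, denom, expected):
        # synthesize a matchset with the requested coverage fraction
        from seqrules.biomeasures import MatchSet
        covered = frozenset(f"G{i}" for i in range(n_covered))
        ms = MatchSet(namespace="BP", matches=[("T", covered)],
                      n_rule_genes=denom)
        assert assign_category(ms) == expected

    def test_no_match_is_category_five(self):
        from seqrules.biomeasures import MatchSet
        assert assign_category(MatchSet(namespace="BP")) == 5

    def test_points_sum_covered_genes(self):
        from seqrules.biomeasures import MatchSet
        ms = MatchSet(namespace="BP", matches=[
            ("T1", frozenset({"g1", "g2"})),
            ("T5", frozenset({"g1", "g2", "g3"}))], n_rule_genes=3)
        assert compute_points(ms) == 5
        assert compute_points(MatchSet(namespace="BP")) == 0


class TestScoreRuleset:
    def _scored(self, ann_map, rules):
        rs = RuleSet("g", rules)
        score_ruleset(rs, _annotation(ann_map), "BP")
        return [r.bio["bp"] for r in rs]

    def test_worked_example(self):
        # categories/points: r1 cat1 NP2, r2 cat3 NP2, r3 cat5 NP0
        r1 = make_rule([("p1", 2, "G1")], [("p2", 1, "G2")], 3, 3, 3, 4)
        r2 = make_rule([("a1", 2, "H1"), ("a3", 2, "H3")],
                       [("a2", 1, "H2"), ("a4", 1, "H4")], 3, 3, 3, 4)
        r3 = make_rule([("b1", 2, "K1")], [("b2", 1, "K2")], 3, 3, 3, 4)
        ann = {"G1": {"T1"}, "G2": {"T1"},
               "H1": {"T2"}, "H2": {"T2"},  # 2 of 4 genes -> cat 3
               "K1": {"T9"}}
        scores = self._scored(ann, [r1, r2, r3])
        assert scores[0] == pytest.approx(1 + (1 - 2 / 3))
        assert scores[1] == pytest.approx(3 + (1 - 2 / 3))
        assert scores[2] == pytest.approx(6.0)

    def test_single_rule_max_np_is_own(self):
        r = make_rule([("p1", 2, "G1")], [("p2", 1, "G2")], 3, 3, 3, 4)
        scores = self._scored({"G1": {"T1", "T2"}, "G2": {"T1", "T2"}}, [r])
        # cat 1, NP = 4 -> score 1 + 1/(4+1)
        assert scores[0] == pytest.approx(1 + 1 / 5)

    def test_all_category_five_scores_six(self):
        rules = [make_rule([(f"p{i}", 2, f"G{i}")],
                           [(f"q{i}", 1, f"H{i}")], 3, 3, 3, 4)
                 for i in range(3)]
        assert self._scored({}, rules) == [6.0, 6.0, 6.0]

    def test_empty_ruleset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score_ruleset(RuleSet("g", []), _annotation({}), "BP")

    def test_permutation_invariance(self):
        rules = [
            make_rule([("p1", 2, "G1")], [("p2", 1, "G2")], 3, 3, 3, 4),
            make_rule([("p3", 2, "G3")], [("p4", 1, "G4")], 3, 3, 3, 4),
            make_rule([("p5", 2, "G5")], [("p6", 1, "G6")], 3, 3, 3, 4),
        ]
        ann = {"G1": {"T1"}, "G2": {"T1"}, "G3": {"T1", "T3"},
               "G4": {"T1", "T3"}, "G5": {"T9"}}
        baseline = None
        for perm in itertools.permutations(rules):
            rs = RuleSet("g", list(perm))
            scores = score_ruleset(rs, _annotation(ann), "BP")
            if baseline is None:
                baseline = scores
            assert scores == baseline

    def test_more_points_scores_better_within_category(self):
        # both rules cat 1; r2 shares two terms -> strictly lower score
        r1 = make_rule([("p1", 2, "G1")], [("p2", 1, "G2")], 3, 3, 3, 4)
        r2 = make_rule([("p3", 2, "G3")], [("p4", 1, "G4")], 3, 3, 3, 4)
        ann = {"G1": {"T1"}, "G2": {"T1"},
               "G3": {"T2", "T3"}, "G4": {"T2", "T3"}}
        scores = self._scored(ann, [r1, r2])
        assert scores[1] < scores[0]
        for s in scores:
            assert 1.0 < s <= 2.0

    def test_shared_term_never_worsens_category(self):
        r = make_rule([("p1", 2, "G1")], [("p2", 1, "G2")], 3, 3, 3, 4)
        base_cat = assign_category(find_matches(r, _annotation(
            {"G1": {"T0"}, "G2": {"T9"}})))
        richer = assign_category(find_matches(r, _annotation(
            {"G1": {"T0", "TSHARED"}, "G2": {"T9", "TSHARED"}})))
        assert richer <= base_cat


class TestTFScore:
    def _table(self, rows):
        t = TFTable()
        for tf, tg, mode in rows:
            t.add(tf, tg, mode)
        return t

    def test_direction_match_scores_three(self):
        # down-regulated repressor -> de-repressed (up) target
        table = self._table([("TF1", "G2", "Repression")])
        rule = make_rule([("p1", 1, "TF1")], [("p2", 2, "G2")], 3, 3, 3, 4)
        assert tf_score(rule, table) == 3

    def test_unknown_mode_caps_at_two(self):
        table = self._table([("TF4", "G5", "Unknown")])
        rule = make_rule([("p1", 1, "TF4")], [("p2", 1, "G5")], 3, 3, 3, 4)
        assert tf_score(rule, table) == 2

    def test_tf_without_listed_target_scores_one(self):
        table = self._table([("TFX", "GY", "Activation")])
        rule = make_rule([("p1", 2, "TFX")], [("p2", 2, "GZ")], 3, 3, 3, 4)
        assert tf_score(rule, table) == 1

    def test_no_lhs_tf_scores_zero(self):
        table = self._table([("TF1", "G2", "Activation")])
        rule = make_rule([("p1", 2, "G9")], [("p2", 2, "G2")], 3, 3, 3, 4)
        assert tf_score(rule, table) == 0

    def test_activation_needs_same_direction(self):
        table = self._table([("TF1", "G2", "Activation")])
        same = make_rule([("p1", 2, "TF1")], [("p2", 2, "G2")], 3, 3, 3, 4)
        diff = make_rule([("p1", 2, "TF1")], [("p2", 1, "G2")], 3, 3, 3, 4)
        assert tf_score(same, table) == 3
        assert tf_score(diff, table) == 2

    def test_monotone_in_table_content(self):
        rule = make_rule([("p1", 1, "TF1")], [("p2", 2, "G2")], 3, 3, 3, 4)
        rows = [("TF1", "G9", "Activation"), ("TF1", "G2", "Unknown"),
                ("TF1", "G2", "Repression")]
        last = 0
        for k in range(len(rows) + 1):
            score = tf_score(rule, self._table(rows[:k]))
            assert score >= last
            last = score

    def test_best_pair_wins(self):
        table = self._table([("TF1", "G2", "Repression"),
                             ("TF9", "G3", "Unknown")])
        rule = make_rule([("p1", 1, "TF1"), ("p9", 2, "TF9")],
                         [("p2", 2, "G2"), ("p3", 1, "G3")], 3, 3, 3, 4)
        assert tf_score(rule, table) == 3


class TestScorerAndReport:
    def test_biological_scorer_fills_all_fields(self, toy_ruleset):
        ann = {"BP": _annotation({"G1": {"T1"}, "G2": {"T1"}}, "BP"),
               "SP": _annotation({"G1": {"P1"}, "G2": {"P1"}}, "SP")}
        tft = TFTable()
        tft.add("G1", "G2", "Repression")
        scored = BiologicalScorer(annotations=ann, tf_table=tft) \
            .fit(toy_ruleset).transform(toy_ruleset)
        for rule in scored:
            assert {"bp", "sp", "tf"} <= set(rule.bio)
            assert 1.0 < rule.bio["bp"] <= 6.0

    def test_match_report_round_trip(self, tmp_path, toy_ruleset):
        ann = {"BP": _annotation({"G1": {"T1"}, "G2": {"T1"}}, "BP")}
        score_ruleset(toy_ruleset, ann["BP"], "BP")
        path = tmp_path / "report.xml"
        write_match_report(toy_ruleset, ann, path)
        records = read_match_report(path)
        assert len(records) == len(toy_ruleset)
        # first toy rule links G1 -> G2 through T1
        matched = [r for r in records if r["matches"]]
        assert matched
        assert matched[0]["matches"][("BP", "T1")] == {"G1", "G2"}
        # rules with no matches keep their element with zero children
        unmatched = [r for r in records if not r["matches"]]
        assert unmatched
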