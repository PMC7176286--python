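"""Biological quality measures per rule: annotation coherence and TF cascade.

Four measures (BP, MF, CC from the GO namespaces, SP from pathway sets) rate
how coherently a rule's genes share annotation terms *across* the rule: only
"cross terms" — terms annotating at least one LHS gene and at least one RHS
gene — count, so a rule whose sides share nothing scores worst no matter how
well-annotated each side is on its own.  Genes are deduplicated (two probes
of one gene count once).  With

* ``f_best`` = the largest fraction of the rule's distinct genes covered by
  any single cross term,
* category CAT in 1..5 from ``f_best`` bands (1: all genes share a term;
  2: >= 0.75; 3: >= 0.5; 4: any cross match below 0.5; 5: no cross match),
* points NP = total genes covered, summed over all cross terms,

the ranking score is ``CAT + (1 - NP / (maxNP_in_category + 1))`` where the
max is taken within the rule's category over the whole rule set (scores are
corpus-relative).  Scores lie in (1, 6]; lower is better; a category-5 rule
with no matches scores exactly 6.

The TF measure in {0, 1, 2, 3} rates agreement with a TF -> target table:
1 if any LHS gene is a listed TF; 2 if additionally some RHS gene is that
TF's target; 3 if additionally the regulation mode matches the discrete
directions (Activation: same state on both sides; Repression: opposite;
Unknown never direction-matches).  The score is the highest milestone
attained over all (LHS TF, RHS target) pairs.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import AnnotationTable, RuleSet, SequentialRule, TFTable

__all__ = [
    "MatchSet",
    "find_matches",
    "assign_category",
    "compute_points",
    "score_ruleset",
    "tf_score",
    "BiologicalScorer",
    "write_match_report",
    "read_match_report",
]

#: Category bands on f_best: (category, inclusive lower bound).
DEFAULT_BANDS = ((1, 1.0), (2, 0.75), (3, 0.5))


@dataclass
class MatchSet:
    """Cross-term matches of one rule in one namespace."""

    namespace: str
    matches: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    n_rule_genes: int = 0

    @property
    def f_best(self) -> float | None:
        """Best coverage fraction over cross terms; None with no match."""
        if not self.matches:
            return None
        return max(len(g) for _, g in self.matches) / self.n_rule_genes


def find_matches(rule: SequentialRule, annotation: AnnotationTable) -> MatchSet:
    """Cross terms of ``rule``: terms annotating >= 1 LHS and >= 1 RHS gene,
    each with the full set of rule genes it covers."""
    lhs_genes = rule.genes("lhs")
    rhs_genes = rule.genes("rhs")
    all_genes = lhs_genes | rhs_genes
    lhs_terms = set().union(*(annotation.terms(g) for g in lhs_genes))
    rhs_terms = set().union(*(annotation.terms(g) for g in rhs_genes))
    matches = []
    for term in sorted(lhs_terms & rhs_terms):
        covered = frozenset(g for g in all_genes if term in annotation.terms(g))
        matches.append((term, covered))
    return MatchSet(namespace=annotation.namespace, matches=matches,
                    n_rule_genes=len(all_genes))


def assign_category(matchset: MatchSet, bands=DEFAULT_BANDS) -> int:
    """Category 1 (best) .. 5 (no cross match) from the f_best bands."""
    f = matchset.f_best
    if f is None:
        return 5
    for cat, bound in bands:
        if f >= bound:
            return cat
    return 4


def compute_points(matchset: MatchSet) -> int:
    """NP = total number of covered genes summed over cross terms."""
    return sum(len(genes) for _, genes in matchset.matches)


def score_ruleset(ruleset: RuleSet, annotation: AnnotationTable,
                  namespace: str | None = None,
                  bands=DEFAULT_BANDS) -> dict[tuple[str, str], float]:
    """Corpus-relative ranking scores for every rule in the set.

    Writes each score into ``rule.bio[namespace.lower()]`` and returns a
    mapping from rule key to score.  The whole set must be supplied because
    maxNP is taken within each category over the set.
    """
    if len(ruleset) == 0:
        raise ValueError("cannot score an empty rule set")
    namespace = (namespace or annotation.namespace).lower()
    cats, points = {}, {}
    for rule in ruleset:
        ms = find_matches(rule, annotation)
        cats[id(rule)] = assign_category(ms, bands)
        points[id(rule)] = compute_points(ms)
    max_np: dict[int, int] = {}
    for rule in ruleset:
        c = cats[id(rule)]
        max_np[c] = max(max_np.get(c, 0), points[id(rule)])
    scores: dict[tuple[str, str], float] = {}
    for rule in ruleset:
        c, np_ = cats[id(rule)], points[id(rule)]
        score = c + (1.0 - np_ / (max_np[c] + 1))
        rule.bio[namespace] = score
        scores[rule.key()] = score
    return scores


def tf_score(rule: SequentialRule, tf_table: TFTable) -> int:
    """Highest TF-cascade milestone attained by the rule (see module docs)."""
    best = 0
    for lhs_item in rule.lhs:
        tf = lhs_item.gene
        if tf is None:
            raise ValueError("rule items lack gene symbols")
        if tf not in tf_table.tfs:
            continue
        best = max(best, 1)
        targets = tf_table.targets(tf)
        for rhs_item in rule.rhs:
            if rhs_item.gene not in targets:
                continue
            best = max(best, 2)
            for mode in tf_table.modes(tf, rhs_item.gene):
                if mode == "Activation" and rhs_item.state == lhs_item.state:
                    return 3
                if mode == "Repression" and rhs_item.state != lhs_item.state:
                    return 3
    return best


class BiologicalScorer(BaseEstimator, TransformerMixin):
    """Stateless transformer attaching the five biological measures to a
    :class:`RuleSet`.

    Parameters
    ----------
    annotations : mapping namespace -> AnnotationTable
        Any subset of {"BP", "MF", "CC", "SP"}; missing namespaces are
        simply not scored.
    tf_table : TFTable or None
        TF -> target regulation table for the TF measure.
    bands : tuple
        (category, lower f_best bound) bands, configurable.
    """

    def __init__(self, annotations: dict[str, AnnotationTable] | None = None,
                 tf_table: TFTable | None = None, bands=DEFAULT_BANDS):
        self.annotations = annotations
        self.tf_table = tf_table
        self.bands = bands

    def fit(self, X: RuleSet, y=None) -> "BiologicalScorer":
        return self

    def transform(self, X: RuleSet) -> RuleSet:
        for namespace, table in (self.annotations or {}).items():
            score_ruleset(X, table, namespace=namespace, bands=self.bands)
        if self.tf_table is not None:
            for rule in X:
                rule.bio["tf"] = float(tf_score(rule, self.tf_table))
        return X


def write_match_report(ruleset: RuleSet,
                       annotations: dict[str, AnnotationTable],
                       path) -> None:
    """XML report detailing every cross-term match of every rule.

    One ``<rule>`` element per rule (metrics and biological scores as
    attributes) with nested ``<match namespace=... term=...>`` elements
    listing the covered genes.  Rules with no matches keep their element
    with zero match children.
    """
    root = ET.Element("rule_match_report", group=str(ruleset.group))
    for rule in ruleset:
        m = rule.metrics
        attrs = {
            "lhs": " & ".join(str(i) for i in sorted(rule.lhs)),
            "rhs": " & ".join(str(i) for i in sorted(rule.rhs)),
            "sup_count": str(rule.sup_seq),
            "seq_sup": f"{m.seq_sup:.6g}",
            "seq_conf": f"{m.seq_conf:.6g}",
            "lift": f"{m.lift:.6g}",
            "cf": f"{m.cf:.6g}",
            "conviction": "Inf" if m.conviction == float("inf")
                          else f"{m.conviction:.6g}",
        }
        for name, value in sorted(rule.bio.items()):
            attrs[name] = f"{value:.6g}"
        elem = ET.SubElement(root, "rule", attrs)
        for namespace in sorted(annotations):
            ms = find_matches(rule, annotations[namespace])
            for term, genes in ms.matches:
                match = ET.SubElement(elem, "match",
                                      namespace=namespace, term=term)
                for gene in sorted(genes):
                    ET.SubElement(match, "gene").text = gene
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_match_report(path) -> list[dict]:
    """Re-parse a match report into one record per rule:
    ``{"lhs": str, "rhs": str, "matches": {(namespace, term): set(genes)}}``.
    """
    root = ET.parse(path).getroot()
    out = []
    for elem in root.findall("rule"):
        matches: dict[tuple[str, str], set[str]] = {}
        for match in elem.findall("match"):
            key = (match.get("namespace"), match.get("term"))
            matches[key] = {g.text for g in match.findall("gene")}
        out.append({"lhs": elem.get("lhs"), "rhs": elem.get("rhs"),
                    "matches": matches})
    return out
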