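"""Two-phase sequential rule mining over multi-subject sequence databases.

The miner follows the CMRules strategy: because the ordered (sequential)
support of a rule can never exceed the unordered association support of its
items in the flattened sequences — and sequential confidence can never
exceed association confidence — candidate rules can first be generated
cheaply by a classical Apriori pass over the flattened database, and the
exact sequential counts computed only for those survivors.

Phase 1 (candidate generation)
    Flatten each sequence to the union of its itemsets; run levelwise
    Apriori at ``min_sup_frac = min_seq_sup``; split each frequent itemset
    into every (LHS, RHS) pair of non-empty disjoint parts whose association
    confidence reaches ``min_seq_conf``.

Phase 2 (sequential counting)
    A sequence supports LHS -> RHS when there is a cut position k such that
    all LHS items occur in itemsets 1..k and all RHS items in itemsets
    k+1..n.  Items within one side need not share an itemset or an order.
    Rules whose sequential support and confidence reach the thresholds
    (inclusively) are returned with all five metrics.

The module also implements the very-strong-rule filter, the two-group
contrast miner (rules exclusive to one experimental group), and gene-level
replication matching across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator

from .data_model import RuleSet, SequentialRule, _sort_rules
from .metrics import rule_metrics as compute_rule_metrics  # noqa: F401
from .seqdb import SequenceDatabase

__all__ = [
    "FrequentItemset",
    "mine_frequent_itemsets",
    "generate_candidate_rules",
    "sequence_contains",
    "compute_rule_metrics",
    "mine_sequential_rules",
    "SequentialRuleMiner",
    "filter_very_strong",
    "mine_contrast",
    "match_rules",
]


@dataclass(frozen=True)
class FrequentItemset:
    """An itemset together with its flattened-transaction count."""

    items: frozenset[int]
    count: int
    frac: float


def _flatten(seqdb: SequenceDatabase) -> list[frozenset[int]]:
    return [frozenset().union(*seq) if seq else frozenset()
            for seq in seqdb.sequences]


def mine_frequent_itemsets(
    seqdb: SequenceDatabase,
    min_sup_frac: float,
    max_size: int | None = None,
) -> list[FrequentItemset]:
    """Levelwise Apriori over the flattened sequences.

    Returns all (and only) itemsets whose fraction of flattened transactions
    is ``>= min_sup_frac``, up to ``max_size`` items per set.
    """
    if len(seqdb) == 0:
        raise ValueError("empty sequence database")
    if not 0 < min_sup_frac <= 1:
        raise ValueError("min_sup_frac must be in (0, 1]")
    transactions = _flatten(seqdb)
    n = len(transactions)
    min_count = min_sup_frac * n

    counts: dict[frozenset[int], int] = {}
    for t in transactions:
        for item in t:
            key = frozenset((item,))
            counts[key] = counts.get(key, 0) + 1
    level = {s: c for s, c in counts.items() if c >= min_count}
    frequent = dict(level)

    k = 1
    while level and (max_size is None or k < max_size):
        k += 1
        # join step: union pairs from the previous level, keep size-k sets
        candidates: set[frozenset[int]] = set()
        prev = list(level)
        for a, b in combinations(prev, 2):
            u = a | b
            if len(u) == k:
                candidates.add(u)
        # prune step: every (k-1)-subset must be frequent
        pruned = {
            c for c in candidates
            if all(frozenset(sub) in level
                   for sub in combinations(c, k - 1))
        }
        level = {}
        for c in pruned:
            count = sum(1 for t in transactions if c <= t)
            if count >= min_count:
                level[c] = count
        frequent.update(level)

    return [FrequentItemset(items=s, count=c, frac=c / n)
            for s, c in frequent.items()]


def generate_candidate_rules(
    frequent: Sequence[FrequentItemset],
    min_conf: float,
    max_lhs: int | None = None,
    max_rhs: int | None = None,
) -> list[tuple[frozenset[int], frozenset[int]]]:
    """Split every frequent itemset into all (LHS, RHS) pairs of non-empty
    disjoint parts with association confidence >= ``min_conf``."""
    counts = {fi.items: fi.count for fi in frequent}
    rules: list[tuple[frozenset[int], frozenset[int]]] = []
    for fi in frequent:
        items = fi.items
        if len(items) < 2:
            continue
        for r in range(1, len(items)):
            if max_lhs is not None and r > max_lhs:
                continue
            if max_rhs is not None and len(items) - r > max_rhs:
                continue
            for lhs in combinations(sorted(items), r):
                lhs_set = frozenset(lhs)
                lhs_count = counts.get(lhs_set)
                if lhs_count is None:
                    continue  # cannot happen under anti-monotonicity
                if fi.count / lhs_count >= min_conf:
                    rules.append((lhs_set, items - lhs_set))
    return rules


def sequence_contains(sequence: Sequence[Iterable[int]],
                      lhs: Iterable[int], rhs: Iterable[int]) -> bool:
    """True iff there is a cut position k (1 <= k <= n-1) such that all LHS
    items occur in itemsets 1..k and all RHS items in itemsets k+1..n.
    A single-itemset sequence can never contain a rule (no cut exists)."""
    lhs = frozenset(lhs)
    rhs = frozenset(rhs)
    n = len(sequence)
    if n < 2:
        return False
    suffix: list[frozenset[int]] = [frozenset()] * n
    acc: frozenset[int] = frozenset()
    for i in range(n - 1, -1, -1):
        acc = acc | frozenset(sequence[i])
        suffix[i] = acc
    prefix: frozenset[int] = frozenset()
    for k in range(n - 1):
        prefix = prefix | frozenset(sequence[k])
        if lhs <= prefix and rhs <= suffix[k + 1]:
            return True
    return False


def _sequential_counts(seqdb: SequenceDatabase, lhs: frozenset[int],
                       rhs: frozenset[int]) -> tuple[int, int, int, int]:
    """(sup_seq, sup_lhs, sup_rhs, n_neither) for one rule by direct scan."""
    sup_seq = sup_lhs = sup_rhs = n_neither = 0
    for seq in seqdb.sequences:
        flat = frozenset().union(*seq) if seq else frozenset()
        has_l = lhs <= flat
        has_r = rhs <= flat
        sup_lhs += has_l
        sup_rhs += has_r
        if not has_l and not has_r:
            n_neither += 1
        if has_l and has_r and sequence_contains(seq, lhs, rhs):
            sup_seq += 1
    return sup_seq, sup_lhs, sup_rhs, n_neither


def _make_rule(seqdb: SequenceDatabase, lhs: frozenset[int],
               rhs: frozenset[int], counts: tuple[int, int, int, int]
               ) -> SequentialRule:
    sup_seq, sup_lhs, sup_rhs, n_neither = counts
    return SequentialRule(
        lhs=frozenset(seqdb.item(i) for i in lhs),
        rhs=frozenset(seqdb.item(i) for i in rhs),
        sup_seq=sup_seq, sup_lhs=sup_lhs, sup_rhs=sup_rhs,
        n_sequences=len(seqdb), n_neither=n_neither,
    )


class SequentialRuleMiner(BaseEstimator):
    """Mine sequential rules from a :class:`SequenceDatabase`.

    Parameters
    ----------
    min_seq_sup, min_seq_conf : float in (0, 1]
        Inclusive thresholds on sequential support and confidence.
    max_itemset_size : int or None
        Cap on the Apriori lattice depth (candidate-explosion control);
        ``None`` explores the full lattice.
    max_lhs, max_rhs : int or None
        Optional caps on the number of items per rule side.

    Attributes
    ----------
    frequent_itemsets_ : list[FrequentItemset]
        Phase-1 output on the flattened database.
    rules_ : RuleSet
        The mined rules, deterministically ordered (descending confidence,
        support, then lexicographic itemsets).
    n_sequences_ : int
        |SD| of the fitted database.
    """

    def __init__(self, min_seq_sup: float = 0.5, min_seq_conf: float = 0.6,
                 max_itemset_size: int | None = 4,
                 max_lhs: int | None = None, max_rhs: int | None = None):
        self.min_seq_sup = min_seq_sup
        self.min_seq_conf = min_seq_conf
        self.max_itemset_size = max_itemset_size
        self.max_lhs = max_lhs
        self.max_rhs = max_rhs

    def fit(self, X: SequenceDatabase, y=None) -> "SequentialRuleMiner":
        if not 0 < self.min_seq_sup <= 1 or not 0 < self.min_seq_conf <= 1:
            raise ValueError("thresholds must be in (0, 1]")
        if len(X) == 0:
            raise ValueError("empty sequence database")
        self.n_sequences_ = len(X)
        self.frequent_itemsets_ = mine_frequent_itemsets(
            X, self.min_seq_sup, max_size=self.max_itemset_size)
        candidates = generate_candidate_rules(
            self.frequent_itemsets_, self.min_seq_conf,
            max_lhs=self.max_lhs, max_rhs=self.max_rhs)
        rules = []
        for lhs, rhs in candidates:
            counts = _sequential_counts(X, lhs, rhs)
            sup_seq, sup_lhs, _, _ = counts
            if sup_lhs == 0:
                continue
            if (sup_seq / len(X) >= self.min_seq_sup
                    and sup_seq / sup_lhs >= self.min_seq_conf):
                rules.append(_make_rule(X, lhs, rhs, counts))
        self.rules_ = RuleSet(group=X.group, rules=_sort_rules(rules))
        return self

    def evaluate(self, X: SequenceDatabase, lhs: frozenset[int],
                 rhs: frozenset[int]) -> SequentialRule | None:
        """Exact counts of an arbitrary rule in ``X`` (used for contrast
        mining); ``None`` when the LHS never occurs."""
        counts = _sequential_counts(X, lhs, rhs)
        if counts[1] == 0:
            return None
        return _make_rule(X, lhs, rhs, counts)


def mine_sequential_rules(seqdb: SequenceDatabase, min_seq_sup: float,
                          min_seq_conf: float, max_lhs: int | None = None,
                          max_rhs: int | None = None,
                          max_itemset_size: int | None = 4) -> RuleSet:
    """Functional front door over :class:`SequentialRuleMiner`."""
    miner = SequentialRuleMiner(
        min_seq_sup=min_seq_sup, min_seq_conf=min_seq_conf,
        max_itemset_size=max_itemset_size, max_lhs=max_lhs, max_rhs=max_rhs)
    return miner.fit(seqdb).rules_


def filter_very_strong(ruleset: RuleSet, min_seq_sup: float,
                       variant: str = "cf_only",
                       not_sup_threshold: float | None = None) -> RuleSet:
    """Keep only "very strong" rules.

    ``cf_only`` (default): seq_sup > min_seq_sup and CF > 0.
    ``literal``: additionally require the fraction of sequences containing
    neither side to exceed 1 - min_seq_sup (the textual counter-reciprocal
    condition; arithmetically unsatisfiable for min_seq_sup < 0.5).
    ``counter_reciprocal``: require that fraction to exceed a user-chosen
    ``not_sup_threshold`` instead.
    """
    if variant not in {"cf_only", "literal", "counter_reciprocal"}:
        raise ValueError(f"unknown very-strong variant {variant!r}")
    if variant == "counter_reciprocal" and not_sup_threshold is None:
        raise ValueError("counter_reciprocal variant needs not_sup_threshold")
    kept = []
    for rule in ruleset:
        if not (rule.seq_sup > min_seq_sup and rule.cf > 0):
            continue
        if variant == "literal":
            if rule.notsup_frac <= 1 - min_seq_sup:
                continue
        elif variant == "counter_reciprocal":
            if rule.notsup_frac <= not_sup_threshold:
                continue
        kept.append(rule)
    return RuleSet(group=ruleset.group, rules=kept)


def _codebooks_compatible(a: SequenceDatabase, b: SequenceDatabase) -> bool:
    if a.codebook is None or b.codebook is None:
        return True  # raw SPMF input: codes are the shared vocabulary
    return (a.codebook.probe_ids == b.codebook.probe_ids
            and a.codebook.width == b.codebook.width)


def _codes(seqdb: SequenceDatabase, rule: SequentialRule
           ) -> tuple[frozenset[int], frozenset[int]]:
    cb = seqdb.codebook
    if cb is None:
        return (frozenset(int(i.probe) for i in rule.lhs),
                frozenset(int(i.probe) for i in rule.rhs))
    return (frozenset(cb.encode(i.state, i.probe) for i in rule.lhs),
            frozenset(cb.encode(i.state, i.probe) for i in rule.rhs))


def mine_contrast(seqdb_a: SequenceDatabase, seqdb_b: SequenceDatabase,
                  min_seq_sup: float, min_seq_conf: float,
                  max_itemset_size: int | None = 4
                  ) -> tuple[RuleSet, RuleSet]:
    """Rules exclusive to each experimental group.

    A rule lands in ``rules_only_a`` iff it passes both thresholds in A and
    fails at least one of them in B (and symmetrically); rules passing in
    both groups appear in neither output.
    """
    if not _codebooks_compatible(seqdb_a, seqdb_b):
        raise ValueError("incompatible item codebooks between groups")

    def passes_in(rule: SequentialRule, db: SequenceDatabase,
                  miner: SequentialRuleMiner) -> bool:
        lhs, rhs = _codes(db, rule)
        other = miner.evaluate(db, lhs, rhs)
        if other is None:
            return False
        return (other.seq_sup >= min_seq_sup
                and other.seq_conf >= min_seq_conf)

    miner = SequentialRuleMiner(min_seq_sup=min_seq_sup,
                                min_seq_conf=min_seq_conf,
                                max_itemset_size=max_itemset_size)
    rules_a = mine_sequential_rules(seqdb_a, min_seq_sup, min_seq_conf,
                                    max_itemset_size=max_itemset_size)
    rules_b = mine_sequential_rules(seqdb_b, min_seq_sup, min_seq_conf,
                                    max_itemset_size=max_itemset_size)
    only_a = [r for r in rules_a if not passes_in(r, seqdb_b, miner)]
    only_b = [r for r in rules_b if not passes_in(r, seqdb_a, miner)]
    return (RuleSet(group=seqdb_a.group, rules=only_a),
            RuleSet(group=seqdb_b.group, rules=only_b))


def match_rules(rulesets: Sequence[RuleSet], ignore_state: bool = False
                ) -> list[list[tuple[str, SequentialRule]]]:
    """Replication groups across datasets.

    Two rules replicate when their LHS gene(+state) sets and RHS gene(+state)
    sets coincide after dropping probe identifiers; with ``ignore_state`` the
    up/down states are dropped too (catching e.g. a down->down pattern in one
    cohort replicated as up->up in another).  Returns groups of >= 2 rules
    spanning >= 2 datasets, each entry tagged with its rule set's label.
    """
    if len(rulesets) < 2:
        raise ValueError("replication matching needs >= 2 rule sets")
    buckets: dict[tuple, list[tuple[int, str, SequentialRule]]] = {}
    for idx, rs in enumerate(rulesets):
        for rule in rs:
            sig = rule.signature(ignore_state=ignore_state)
            buckets.setdefault(sig, []).append((idx, rs.group, rule))
    groups = []
    for members in buckets.values():
        datasets = {idx for idx, _, _ in members}
        if len(members) >= 2 and len(datasets) >= 2:
            groups.append([(label, rule) for _, label, rule in members])
    groups.sort(key=lambda g: (str(g[0][1]), g[0][0]))
    return groups
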