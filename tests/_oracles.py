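"""Independent brute-force oracles for the sequential rule miner.

These deliberately share no code with the package: containment is decided
by direct cut-point scanning, frequent itemsets by a powerset scan, and the
rule search enumerates every (LHS, RHS) pair of disjoint non-empty subsets
of the item universe.  Only feasible for tiny databases (<= ~8 items).
"""

from itertools import chain, combinations


def powerset(items, min_size=1):
    items = sorted(items)
    return chain.from_iterable(
        combinations(items, r) for r in range(min_size, len(items) + 1))


def bf_contains(sequence, lhs, rhs):
    """Direct cut-point scan: lhs within itemsets 1..k, rhs within k+1..n."""
    n = len(sequence)
    for k in range(1, n):
        prefix = set().union(*sequence[:k]) if k else set()
        suffix = set().union(*sequence[k:])
        if lhs <= prefix and rhs <= suffix:
            return True
    return False


def bf_frequent_itemsets(sequences, min_sup_frac):
    """All itemsets meeting min support in the flattened transactions."""
    transactions = [set().union(*seq) if seq else set() for seq in sequences]
    universe = set().union(*transactions) if transactions else set()
    n = len(transactions)
    out = {}
    for subset in powerset(universe):
        s = frozenset(subset)
        count = sum(1 for t in transactions if s <= t)
        if count >= min_sup_frac * n:
            out[s] = count
    return out


def bf_mine_rules(sequences, min_seq_sup, min_seq_conf):
    """Every rule meeting both sequential thresholds, with all its counts.

    Returns {(lhs, rhs): (sup_seq, sup_lhs, sup_rhs, n_neither)} over frozen
    integer itemsets.
    """
    flats = [set().union(*seq) if seq else set() for seq in sequences]
    universe = sorted(set().union(*flats)) if flats else []
    n = len(sequences)
    out = {}
    for lhs_tuple in powerset(universe):
        lhs = frozenset(lhs_tuple)
        rest = [i for i in universe if i not in lhs]
        for rhs_tuple in powerset(rest):
            rhs = frozenset(rhs_tuple)
            sup_seq = sup_lhs = sup_rhs = n_neither = 0
            for seq, flat in zip(sequences, flats):
                has_l = lhs <= flat
                has_r = rhs <= flat
                sup_lhs += has_l
                sup_rhs += has_r
                if not has_l and not has_r:
                    n_neither += 1
                if has_l and has_r and bf_contains(seq, lhs, rhs):
                    sup_seq += 1
            if sup_lhs == 0:
                continue
            if (sup_seq >= min_seq_sup * n
                    and sup_seq / sup_lhs >= min_seq_conf):
                out[(lhs, rhs)] = (sup_seq, sup_lhs, sup_rhs, n_neither)
    return out


def random_database(rng, max_items=8, max_sequences=6, max_itemsets=3):
    """A random sequence database over valid item codes (width 1)."""
    n_items = rng.integers(2, max_items + 1)
    # codes: state digit 1 or 2 + single index digit -> always decodable
    alphabet = [(1 + (i % 2)) * 10 + i % 10 for i in range(n_items)]
    alphabet = sorted(set(alphabet))
    n_seq = rng.integers(1, max_sequences + 1)
    sequences = []
    for _ in range(n_seq):
        n_sets = rng.integers(1, max_itemsets + 1)
        seq = []
        for _ in range(n_sets):
            mask = rng.random(len(alphabet)) < 0.35
            seq.append(frozenset(a for a, m in zip(alphabet, mask) if m))
        sequences.append(seq)
    return sequences
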