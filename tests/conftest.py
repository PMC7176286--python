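import numpy as np
import pandas as pd
import pytest

from seqrules.data_model import ExpressionDataset, RuleItem, RuleSet, \
    SequentialRule
from seqrules.seqdb import SequenceDatabase

# item codes at width 3: first digit = state (2 up / 1 down)
A_UP, B_DOWN, C_UP, D_DOWN = 2001, 1002, 2003, 1004


@pytest.fixture
def db_plus():
    """Four sequences, three of which carry A-up before B-down."""
    seq_ab = [frozenset({A_UP}), frozenset({B_DOWN})]
    seq_cd = [frozenset({C_UP}), frozenset({D_DOWN})]
    return SequenceDatabase(group="plus",
                            sequences=[list(seq_ab), list(seq_ab),
                                       list(seq_ab), list(seq_cd)])


@pytest.fixture
def db_minus():
    """Counts (sup_seq, sup_lhs, sup_rhs) = (2, 3, 4) for A-up -> B-down."""
    return SequenceDatabase(group="minus", sequences=[
        [frozenset({A_UP}), frozenset({B_DOWN})],
        [frozenset({A_UP}), frozenset({B_DOWN})],
        [frozenset({B_DOWN}), frozenset({A_UP})],
        [frozenset({B_DOWN}), frozenset()],
    ])


def make_rule(lhs, rhs, sup_seq, sup_lhs, sup_rhs, n, n_neither=None,
              bio=None):
    """lhs/rhs as iterables of (probe, state, gene) triples."""
    return SequentialRule(
        lhs=frozenset(RuleItem(probe=p, state=s, gene=g) for p, s, g in lhs),
        rhs=frozenset(RuleItem(probe=p, state=s, gene=g) for p, s, g in rhs),
        sup_seq=sup_seq, sup_lhs=sup_lhs, sup_rhs=sup_rhs, n_sequences=n,
        n_neither=n_neither, bio=dict(bio or {}),
    )


@pytest.fixture
def toy_ruleset():
    """Three single-item rules over four genes, with sane counts."""
    rules = [
        make_rule([("p1", 2, "G1")], [("p2", 1, "G2")], 3, 3, 3, 4, 1),
        make_rule([("p1", 2, "G1")], [("p3", 1, "G3")], 2, 3, 4, 4, 0),
        make_rule([("p4", 2, "G4")], [("p2", 1, "G2")], 2, 2, 3, 4, 1),
    ]
    return RuleSet(group="toy", rules=rules)


def make_dataset(values_by_subject, timepoints, groups, probes, genes=None):
    """Small expression dataset; values_by_subject[s] is a (timepoint ->
    list of per-probe values) mapping."""
    cols = {}
    for s, per_tp in values_by_subject.items():
        for tp in timepoints:
            cols[(s, tp)] = per_tp[tp]
    frame = pd.DataFrame(cols, index=probes, dtype=float)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["subject", "timepoint"])
    probe_genes = dict(zip(probes, genes)) if genes else {p: None for p in probes}
    return ExpressionDataset(values=frame, groups=groups,
                             timepoints=list(timepoints),
                             probe_genes=probe_genes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
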