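"""Frequentist quality metrics for sequential rules.

Given the raw sequence counts of a rule LHS -> RHS over a database of ``n``
sequences —

* ``sup_seq``: sequences where all LHS items occur before all RHS items,
* ``sup_lhs`` / ``sup_rhs``: sequences containing the itemset anywhere —

the five metrics are the sequential analogues of the classic association-rule
measures, obtained by substituting the ordered-containment fraction for the
joint support and sequence-containment fractions for the marginal supports:

* ``seq_sup  = sup_seq / n``
* ``seq_conf = sup_seq / sup_lhs``
* ``lift     = seq_sup / ((sup_lhs/n) * (sup_rhs/n))``  (1 = independence)
* ``conviction = (1 - sup_rhs/n) / (1 - seq_conf)``, defined as +inf when
  ``seq_conf = 1`` (perfect implication, including the 0/0 corner)
* certainty factor ``cf``: ``(seq_conf - p_rhs)/(1 - p_rhs)`` when
  ``seq_conf > p_rhs``, ``(seq_conf - p_rhs)/p_rhs`` when below, 0 at
  equality, with ``p_rhs = sup_rhs/n``;  cf lies in [-1, 1] and its sign
  agrees with ``lift - 1``.
"""

from __future__ import annotations

import math
from typing import NamedTuple

__all__ = ["RuleMetrics", "rule_metrics"]


class RuleMetrics(NamedTuple):
    seq_sup: float
    seq_conf: float
    lift: float
    cf: float
    conviction: float


def rule_metrics(sup_seq: int, sup_lhs: int, sup_rhs: int,
                 n_sequences: int) -> RuleMetrics:
    """Compute the five metrics from raw counts.

    Raises ``ValueError`` on inconsistent counts (``sup_seq`` cannot exceed
    either marginal, and marginals cannot exceed ``n``) or ``sup_lhs = 0``.
    """
    n = n_sequences
    if n <= 0:
        raise ValueError("n_sequences must be positive")
    if sup_lhs == 0:
        raise ValueError("sup_lhs = 0: rule confidence is undefined")
    if not (0 <= sup_seq <= min(sup_lhs, sup_rhs) <= max(sup_lhs, sup_rhs) <= n):
        raise ValueError(
            f"inconsistent counts: sup_seq={sup_seq}, sup_lhs={sup_lhs}, "
            f"sup_rhs={sup_rhs}, n={n}"
        )

    seq_sup = sup_seq / n
    seq_conf = sup_seq / sup_lhs
    p_lhs = sup_lhs / n
    p_rhs = sup_rhs / n

    lift = seq_sup / (p_lhs * p_rhs) if sup_rhs else 0.0

    if seq_conf == 1.0:
        conviction = math.inf
    else:
        conviction = (1.0 - p_rhs) / (1.0 - seq_conf)

    if math.isclose(seq_conf, p_rhs, rel_tol=0.0, abs_tol=1e-15):
        cf = 0.0
    elif seq_conf > p_rhs:
        cf = (seq_conf - p_rhs) / (1.0 - p_rhs)
    else:
        cf = (seq_conf - p_rhs) / p_rhs

    return RuleMetrics(seq_sup, seq_conf, lift, cf, conviction)
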