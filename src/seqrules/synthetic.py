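"""Synthetic longitudinal cohorts with planted time-lagged regulation events.

The generator emulates the structure of a two-arm dietary-intervention
microarray study: N subjects per group, 3 (or more) timepoints, M probes on
a log2 scale.  A *planted rule* is a pair of gene-change events with a time
lag — the LHS gene shifts at the second timepoint (and stays shifted), the
RHS gene shifts at the third — carried by a deterministic
``round(penetrance * N)``-subject subset of each targeted group.  Everything
else is i.i.d. Gaussian noise around a per-subject-x-probe baseline, so the
exact carrier subsets (returned as :class:`SimTruth`) make end-to-end
recovery checks exact rather than statistical.

Defaults mirror the discovery cohort's shape (24 subjects per group, 3
timepoints, two intervention arms) with array-like noise of 0.2 log2 units
and a planted effect of 2.5 log2 units.  The effect must clear the
feature-selection gate after penetrance dilution with a margin covering the
noise on every group-mean gate simultaneously: the gate sees
``penetrance * effect`` against the |mean SLR| >= 1 threshold with a
standard error of ``noise_sd * sqrt(2 / n)`` (~0.06), so 2.5 gives
0.6 * 2.5 = 1.5, an ~8-sigma margin that makes recovery deterministic in
practice, while weak (penetrance 0.2) plants stay ~8 sigma below the gate.

Matching annotation/TF tables can be generated so that each planted gene
pair shares a dedicated term per namespace and has a TF -> target row whose
mode is consistent with the planted directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (AnnotationTable, ExpressionDataset, TFTable,
                         normalize_gene)

__all__ = ["PlantedRule", "SimConfig", "SimTruth", "simulate_dataset",
           "simulate_annotations"]

UP, DOWN = 2, 1


@dataclass(frozen=True)
class PlantedRule:
    """A planted time-lagged event pair: LHS gene changes in interval 1,
    RHS gene in interval 2, in ``penetrance * N`` subjects of each targeted
    group (``group=None`` plants in every group)."""

    lhs_gene: str
    lhs_direction: int  # 2 = up, 1 = down
    rhs_gene: str
    rhs_direction: int
    penetrance: float = 0.6
    effect: float = 2.5
    group: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        if self.lhs_direction not in (1, 2) or self.rhs_direction not in (1, 2):
            raise ValueError("directions must be 1 (down) or 2 (up)")
        object.__setattr__(self, "lhs_gene", normalize_gene(self.lhs_gene))
        object.__setattr__(self, "rhs_gene", normalize_gene(self.rhs_gene))


@dataclass
class SimConfig:
    n_subjects: int = 24          # per group
    n_timepoints: int = 3
    n_probes: int = 200
    groups: tuple[str, ...] = ("LCD", "VLCD")
    baseline_mean: float = 7.0    # log2 scale, typical array intensity
    baseline_sd: float = 1.0
    noise_sd: float = 0.2
    planted_rules: list[PlantedRule] = field(default_factory=list)
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth: exact carrier subjects per planted rule and group."""

    carriers: dict[int, dict[str, list[str]]]  # rule index -> group -> ids
    probes: dict[str, str]                     # gene -> probe id
    config: SimConfig

    def expected_seq_sup(self, rule_index: int, group: str) -> float:
        return (len(self.carriers[rule_index].get(group, []))
                / self.config.n_subjects)


def _signed(direction: int, effect: float) -> float:
    return effect if direction == UP else -effect


def simulate_dataset(config: SimConfig) -> tuple[ExpressionDataset, SimTruth]:
    """Generate an expression dataset plus its ground truth, deterministic
    for a given config (seed included)."""
    rng = np.random.default_rng(config.seed)
    if config.n_timepoints < 3 and config.planted_rules:
        raise ValueError("planted rules need >= 3 timepoints (two intervals)")

    planted_genes: dict[str, None] = {}
    for pr in config.planted_rules:
        planted_genes.setdefault(pr.lhs_gene, None)
        planted_genes.setdefault(pr.rhs_gene, None)
    if len(planted_genes) > config.n_probes:
        raise ValueError("more planted genes than probes")

    width = max(4, len(str(config.n_probes)))
    probe_ids = [f"p{i:0{width}d}" for i in range(1, config.n_probes + 1)]
    genes = list(planted_genes) + [
        f"GDEC{i:04d}" for i in range(1, config.n_probes - len(planted_genes) + 1)
    ]
    probe_genes = dict(zip(probe_ids, genes))
    gene_probe = {g: p for p, g in probe_genes.items()}

    timepoints = [f"T{i}" for i in range(1, config.n_timepoints + 1)]
    subjects = {
        g: [f"{g}_S{j:02d}" for j in range(1, config.n_subjects + 1)]
        for g in config.groups
    }
    all_subjects = [s for g in config.groups for s in subjects[g]]
    groups = {s: g for g in config.groups for s in subjects[g]}

    n_sub, n_tp, n_pr = len(all_subjects), config.n_timepoints, config.n_probes
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=(n_sub, n_pr))
    values = baseline[:, None, :] + rng.normal(
        0.0, config.noise_sd, size=(n_sub, n_tp, n_pr))

    sub_index = {s: i for i, s in enumerate(all_subjects)}
    probe_index = {p: i for i, p in enumerate(probe_ids)}

    carriers: dict[int, dict[str, list[str]]] = {}
    for ridx, pr in enumerate(config.planted_rules):
        targeted = [pr.group] if pr.group is not None else list(config.groups)
        carriers[ridx] = {}
        for g in targeted:
            if g not in subjects:
                raise ValueError(f"planted rule targets unknown group {g!r}")
            n_carriers = round(pr.penetrance * config.n_subjects)
            order = rng.permutation(config.n_subjects)
            chosen = [subjects[g][k] for k in sorted(order[:n_carriers])]
            carriers[ridx][g] = chosen
            lp = probe_index[gene_probe[pr.lhs_gene]]
            rp = probe_index[gene_probe[pr.rhs_gene]]
            for s in chosen:
                si = sub_index[s]
                # LHS shifts from timepoint 2 on; RHS from timepoint 3 on —
                # each change is specific to one interval
                values[si, 1:, lp] += _signed(pr.lhs_direction, pr.effect)
                values[si, 2:, rp] += _signed(pr.rhs_direction, pr.effect)

    cols = {}
    for s in all_subjects:
        for t, tp in enumerate(timepoints):
            cols[(s, tp)] = values[sub_index[s], t, :]
    frame = pd.DataFrame(cols, index=probe_ids)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["subject", "timepoint"])
    dataset = ExpressionDataset(values=frame, groups=groups,
                                timepoints=timepoints,
                                probe_genes=dict(probe_genes))
    truth = SimTruth(carriers=carriers, probes=gene_probe, config=config)
    return dataset, truth


def simulate_annotations(
    truth: SimTruth,
    n_decoy_terms: int = 10,
    namespaces: tuple[str, ...] = ("BP", "MF", "CC", "SP"),
    seed: int = 0,
) -> tuple[dict[str, AnnotationTable], TFTable]:
    """Annotation and TF tables consistent with the planted rules.

    Each planted gene pair shares a dedicated term in every namespace, and
    gets a TF row whose mode matches the planted directions (same direction
    -> Activation, opposite -> Repression).  Decoy terms and decoy TF rows
    are drawn among non-planted genes only, so they can never create a cross
    match or cascade for a planted rule by construction.
    """
    rng = np.random.default_rng(seed)
    planted = truth.config.planted_rules
    planted_genes = {g for pr in planted for g in (pr.lhs_gene, pr.rhs_gene)}
    decoy_genes = sorted(set(truth.probes) - planted_genes)

    annotations = {ns: AnnotationTable(namespace=ns) for ns in namespaces}
    for ridx, pr in enumerate(planted):
        for ns in namespaces:
            term = f"{ns}_PLANT_{ridx:03d}"
            annotations[ns].add(pr.lhs_gene, term)
            annotations[ns].add(pr.rhs_gene, term)
    for t in range(n_decoy_terms):
        if len(decoy_genes) < 2:
            break
        members = rng.choice(decoy_genes, size=2, replace=False)
        for ns in namespaces:
            for g in members:
                annotations[ns].add(str(g), f"{ns}_DECOY_{t:03d}")

    tf_table = TFTable()
    for pr in planted:
        mode = ("Activation" if pr.lhs_direction == pr.rhs_direction
                else "Repression")
        tf_table.add(pr.lhs_gene, pr.rhs_gene, mode)
    for t in range(min(n_decoy_terms, max(0, len(decoy_genes) - 1))):
        a, b = rng.choice(decoy_genes, size=2, replace=False)
        tf_table.add(str(a), str(b), "Unknown")
    return annotations, tf_table


def default_cohort(seed: int = 0, n_planted: int = 5,
                   penetrance: float = 0.6,
                   weak_penetrance: float | None = None,
                   group: str | None = None) -> SimConfig:
    """The stock benchmark cohort: 2 groups x 24 subjects x 3 timepoints x
    200 probes with ``n_planted`` up->down-style planted rules; optionally a
    second tier of weak-penetrance rules that should NOT be mined."""
    directions = [(UP, DOWN), (DOWN, UP), (UP, UP), (DOWN, DOWN), (UP, DOWN)]
    rules = []
    for i in range(n_planted):
        d = directions[i % len(directions)]
        rules.append(PlantedRule(
            lhs_gene=f"GLHS{i:02d}", lhs_direction=d[0],
            rhs_gene=f"GRHS{i:02d}", rhs_direction=d[1],
            penetrance=penetrance, group=group))
    if weak_penetrance is not None:
        for i in range(n_planted):
            d = directions[i % len(directions)]
            rules.append(PlantedRule(
                lhs_gene=f"GWLHS{i:02d}", lhs_direction=d[0],
                rhs_gene=f"GWRHS{i:02d}", rhs_direction=d[1],
                penetrance=weak_penetrance, group=group))
    return SimConfig(planted_rules=rules, seed=seed)
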