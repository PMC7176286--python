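"""Core domain containers and readers/writers for the pipeline's file formats.

The pipeline moves through a small set of typed containers:

* :class:`ExpressionDataset` — normalized log2 expression indexed by
  (subject, timepoint, probe), with an intervention-group label per subject.
* :class:`IntervalSet` — the ordered time intervals over which changes are
  measured (e.g. weight-loss, weight-stable, and whole-intervention periods).
* :class:`AnnotationTable` — gene → term sets for one annotation namespace
  (GO biological process / molecular function / cellular component, or
  pathways).
* :class:`TFTable` — transcription-factor → target rows with a regulation
  mode (Activation / Repression / Unknown).
* :class:`RuleItem` / :class:`SequentialRule` / :class:`RuleSet` — mined
  sequential rules with their frequentist metrics and biological scores.

All external formats are plain text: TSV matrices and sample sheets, GMT or
two-column TSV annotations, TRRUST-style TF tables, and a documented rule
TSV/JSON-lines format that round-trips losslessly (infinite conviction is
serialized as the literal ``Inf``).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import RuleMetrics, rule_metrics

__all__ = [
    "normalize_gene",
    "ExpressionDataset",
    "Interval",
    "IntervalSet",
    "AnnotationTable",
    "TFTable",
    "RuleItem",
    "SequentialRule",
    "RuleSet",
    "read_expression_matrix",
    "read_annotation",
    "read_tf_table",
    "write_rules",
    "read_rules",
]

#: Biological-score fields carried by a rule, in serialization order.
BIO_FIELDS = ("bp", "mf", "cc", "sp", "tf")

MODES = ("Activation", "Repression", "Unknown")


def normalize_gene(symbol: str | None) -> str | None:
    """Canonical gene-symbol form shared by every module: strip + uppercase."""
    if symbol is None:
        return None
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Normalized log2 expression values for a longitudinal cohort.

    ``values`` is a probes x samples DataFrame whose columns are a MultiIndex
    of ``(subject, timepoint)``; every subject present has a full column for
    every timepoint.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    timepoints: list[str]
    probe_genes: dict[str, str | None]

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("an expression dataset needs at least 2 timepoints")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must all be finite")
        for subject in self.subjects:
            for tp in self.timepoints:
                if (subject, tp) not in self.values.columns:
                    raise ValueError(
                        f"subject {subject!r} is missing timepoint {tp!r}"
                    )

    @property
    def subjects(self) -> list[str]:
        return list(self.groups)

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    def subjects_in_group(self, group: str) -> list[str]:
        out = [s for s, g in self.groups.items() if g == group]
        if not out:
            raise KeyError(f"no subjects in group {group!r}")
        return out

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g, None)
        return list(seen)

    def gene_of(self, probe: str) -> str | None:
        return self.probe_genes.get(probe)


@dataclass(frozen=True)
class Interval:
    """A (from, to) timepoint pair; ``selection_only`` intervals take part in
    feature selection but not in sequence building (they overlap the others)."""

    start: str
    end: str
    label: str
    selection_only: bool = False


@dataclass
class IntervalSet:
    intervals: list[Interval]

    def __post_init__(self) -> None:
        labels = [iv.label for iv in self.intervals]
        if len(labels) != len(set(labels)):
            raise ValueError("interval labels must be unique")

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def mining(self) -> list[Interval]:
        return [iv for iv in self.intervals if not iv.selection_only]

    def validate_against(self, timepoints: Sequence[str]) -> None:
        order = {tp: i for i, tp in enumerate(timepoints)}
        for iv in self.intervals:
            if iv.start not in order or iv.end not in order:
                raise ValueError(
                    f"interval {iv.label!r} endpoint not in dataset timepoints"
                )
            if order[iv.start] >= order[iv.end]:
                raise ValueError(
                    f"interval {iv.label!r}: start must precede end"
                )
        # consecutive mining intervals must tile the timepoint order
        mining = self.mining
        for a, b in zip(mining, mining[1:]):
            if a.end != b.start:
                raise ValueError(
                    "mining intervals must be consecutive and non-overlapping"
                )

    @classmethod
    def consecutive(cls, timepoints: Sequence[str],
                    labels: Sequence[str] | None = None,
                    add_overall: bool = False) -> "IntervalSet":
        """Consecutive intervals over ``timepoints``; optionally an overall
        end-vs-baseline interval flagged ``selection_only``."""
        ivs = []
        for i, (a, b) in enumerate(zip(timepoints, timepoints[1:])):
            label = labels[i] if labels else f"{a}-{b}"
            ivs.append(Interval(a, b, label))
        if add_overall and len(timepoints) > 2:
            ivs.append(Interval(timepoints[0], timepoints[-1],
                                f"{timepoints[0]}-{timepoints[-1]}",
                                selection_only=True))
        return cls(ivs)


def read_expression_matrix(
    matrix_path,
    samplesheet_path,
    probe_map_path=None,
    drop_incomplete: bool = False,
    input_scale: str = "log2",
) -> ExpressionDataset:
    """Read a probes x samples TSV plus a sample sheet into an
    :class:`ExpressionDataset`.

    The sample sheet is a TSV with columns ``sample_id, subject, timepoint,
    group``; every sheet row must name a column of the matrix.  Subjects with
    an incomplete timepoint series are an error unless ``drop_incomplete``
    (they are then excluded with a warning).  ``input_scale="linear"`` applies
    log2 on load for data not already on log scale.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samplesheet_path, sep="\t", dtype=str)
    required = {"sample_id", "subject", "timepoint", "group"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")

    missing = [s for s in sheet["sample_id"] if s not in matrix.columns]
    if missing:
        raise ValueError(f"missing sample column(s) in matrix: {missing}")

    try:
        matrix = matrix.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell: {exc}") from exc
    if input_scale == "linear":
        matrix = np.log2(matrix)
    elif input_scale != "log2":
        raise ValueError("input_scale must be 'log2' or 'linear'")

    timepoints = list(dict.fromkeys(sheet["timepoint"]))
    by_subject: dict[str, dict[str, str]] = {}
    groups: dict[str, str] = {}
    for row in sheet.itertuples(index=False):
        by_subject.setdefault(row.subject, {})[row.timepoint] = row.sample_id
        prev = groups.setdefault(row.subject, row.group)
        if prev != row.group:
            raise ValueError(f"subject {row.subject!r} has conflicting groups")

    incomplete = [s for s, tps in by_subject.items()
                  if set(tps) != set(timepoints)]
    if incomplete:
        if not drop_incomplete:
            raise ValueError(
                f"subject(s) with missing timepoints: {sorted(incomplete)} "
                "(pass drop_incomplete=True to exclude them)"
            )
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) with incomplete "
            f"timepoint series: {sorted(incomplete)}"
        )
        for s in incomplete:
            by_subject.pop(s)
            groups.pop(s)
    if not by_subject:
        raise ValueError("no complete subjects in sample sheet")

    cols = {}
    for subject, tps in by_subject.items():
        for tp in timepoints:
            cols[(subject, tp)] = matrix[tps[tp]]
    values = pd.DataFrame(cols)
    values.columns = pd.MultiIndex.from_tuples(values.columns,
                                               names=["subject", "timepoint"])

    probe_genes: dict[str, str | None] = {p: None for p in matrix.index}
    if probe_map_path is not None:
        pm = pd.read_csv(probe_map_path, sep="\t", dtype=str)
        if pm.shape[1] < 2:
            raise ValueError("probe map needs columns probe_id, gene_symbol")
        for probe, gene in zip(pm.iloc[:, 0], pm.iloc[:, 1]):
            if probe in probe_genes:
                probe_genes[probe] = normalize_gene(gene)

    return ExpressionDataset(values=values, groups=groups,
                             timepoints=timepoints, probe_genes=probe_genes)


# ---------------------------------------------------------------------------
# Annotations and TF tables
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """Gene → set-of-terms map for one namespace (BP, MF, CC or SP)."""

    namespace: str
    _terms: dict[str, set[str]] = field(default_factory=dict)

    def terms(self, gene: str) -> set[str]:
        """Term set of ``gene``; unannotated genes get an empty set."""
        key = normalize_gene(gene)
        return set(self._terms.get(key, set()))

    def add(self, gene: str, term: str) -> None:
        self._terms.setdefault(normalize_gene(gene), set()).add(term)

    @property
    def genes(self) -> set[str]:
        return set(self._terms)


def read_annotation(path, namespace: str) -> AnnotationTable:
    """Read a GMT file (term, description, gene...) or a two-column TSV
    (gene, term) into an :class:`AnnotationTable`.

    The format is sniffed per file: a line with >= 3 fields is GMT, exactly 2
    fields is gene/term.  Mixing the two in one file is rejected.
    """
    table = AnnotationTable(namespace=namespace)
    kind = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed annotation line "
                    f"(needs >= 2 tab-separated fields)"
                )
            this = "gmt" if len(fields) >= 3 else "two_col"
            if kind is None:
                kind = this
            elif kind != this:
                raise ValueError(
                    f"{path}:{lineno}: mixed GMT and two-column lines"
                )
            if this == "gmt":
                term, _desc, *genes = fields
                for gene in genes:
                    if gene:
                        table.add(gene, term)
            else:
                gene, term = fields
                table.add(gene, term)
    return table


@dataclass
class TFTable:
    """Deduplicated (tf, target, mode) rows from a TRRUST-style table.

    Duplicate (tf, target) pairs are merged: an informative mode (Activation
    or Repression) wins over Unknown; conflicting Activation vs Repression
    keeps both rows, so a direction match succeeds if either matches.
    """

    _modes: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def add(self, tf: str, target: str, mode: str) -> None:
        mode = mode.strip().capitalize()
        if mode not in MODES:
            warnings.warn(f"unrecognized TF regulation mode {mode!r} -> Unknown")
            mode = "Unknown"
        key = (normalize_gene(tf), normalize_gene(target))
        modes = self._modes.setdefault(key, set())
        modes.add(mode)
        if len(modes) > 1 and "Unknown" in modes:
            modes.discard("Unknown")  # informative mode wins

    @property
    def rows(self) -> set[tuple[str, str, str]]:
        return {(tf, tg, m) for (tf, tg), ms in self._modes.items() for m in ms}

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self._modes}

    def targets(self, tf: str) -> set[str]:
        tf = normalize_gene(tf)
        return {tg for (t, tg) in self._modes if t == tf}

    def modes(self, tf: str, target: str) -> set[str]:
        return set(self._modes.get(
            (normalize_gene(tf), normalize_gene(target)), set()))

    def __len__(self) -> int:
        return len(self.rows)


def read_tf_table(path) -> TFTable:
    """Read a TSV with columns ``tf, target, mode[, refs...]`` (header
    optional, detected by a first row whose third field is not a mode)."""
    table = TFTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: TF table rows need >= 3 columns"
                )
            tf, target, mode = fields[0], fields[1], fields[2]
            if lineno == 1 and mode.strip().capitalize() not in MODES and (
                    mode.strip().lower() in {"mode", "regulation", "type"}):
                continue  # header row
            table.add(tf, target, mode)
    return table


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class RuleItem:
    """One discrete gene-change event: a probe (or raw item code) together
    with its gene symbol and direction state (1 = decrease, 2 = increase)."""

    probe: str
    state: int
    gene: str | None = field(default=None, compare=True)

    def __post_init__(self) -> None:
        if self.state not in (1, 2):
            raise ValueError("item state must be 1 (down) or 2 (up)")
        object.__setattr__(self, "gene", normalize_gene(self.gene))

    def __str__(self) -> str:
        name = f"{self.probe}/{self.gene}" if self.gene else self.probe
        return f"{name}={self.state}"

    @classmethod
    def parse(cls, text: str) -> "RuleItem":
        name, _, state = text.strip().rpartition("=")
        if not name or not state:
            raise ValueError(f"malformed rule item {text!r}")
        probe, sep, gene = name.partition("/")
        return cls(probe=probe.strip(), state=int(state),
                   gene=gene.strip() if sep else None)


def _format_itemset(items: Iterable[RuleItem]) -> str:
    return " & ".join(str(i) for i in sorted(items))


def _parse_itemset(text: str) -> frozenset[RuleItem]:
    return frozenset(RuleItem.parse(part) for part in text.split("&"))


@dataclass
class SequentialRule:
    """An ordered implication LHS -> RHS over a sequence database, with the
    raw sequence counts it was mined from.

    ``sup_seq`` counts sequences where every LHS item occurs strictly before
    every RHS item; ``sup_lhs``/``sup_rhs`` count sequences containing the
    itemset anywhere; ``n_neither`` counts sequences containing neither side
    (used by the literal very-strong filter).  The five frequentist metrics
    are derived properties.
    """

    lhs: frozenset[RuleItem]
    rhs: frozenset[RuleItem]
    sup_seq: int
    sup_lhs: int
    sup_rhs: int
    n_sequences: int
    n_neither: int | None = None
    bio: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lhs = frozenset(self.lhs)
        self.rhs = frozenset(self.rhs)
        if not self.lhs or not self.rhs:
            raise ValueError("LHS and RHS must be non-empty")
        if self.lhs & self.rhs:
            raise ValueError("LHS and RHS must be disjoint")
        if not (0 <= self.sup_seq <= min(self.sup_lhs, self.sup_rhs)
                <= self.n_sequences):
            raise ValueError("inconsistent rule counts")

    @property
    def metrics(self) -> RuleMetrics:
        return rule_metrics(self.sup_seq, self.sup_lhs, self.sup_rhs,
                            self.n_sequences)

    seq_sup = property(lambda self: self.metrics.seq_sup)
    seq_conf = property(lambda self: self.metrics.seq_conf)
    lift = property(lambda self: self.metrics.lift)
    cf = property(lambda self: self.metrics.cf)
    conviction = property(lambda self: self.metrics.conviction)

    @property
    def notsup_frac(self) -> float:
        if self.n_neither is None:
            raise ValueError("n_neither was not computed for this rule")
        return self.n_neither / self.n_sequences

    def genes(self, side: str | None = None) -> set[str]:
        items: Iterable[RuleItem]
        if side == "lhs":
            items = self.lhs
        elif side == "rhs":
            items = self.rhs
        else:
            items = self.lhs | self.rhs
        genes = {i.gene for i in items}
        if None in genes:
            raise ValueError("rule items lack gene symbols")
        return genes  # type: ignore[return-value]

    def signature(self, ignore_state: bool = False):
        """Gene-level identity used for cross-dataset replication matching."""
        def side(items):
            if ignore_state:
                return frozenset(i.gene for i in items)
            return frozenset((i.gene, i.state) for i in items)
        return side(self.lhs), side(self.rhs)

    def key(self):
        return (_format_itemset(self.lhs), _format_itemset(self.rhs))

    def __str__(self) -> str:
        return f"{{{_format_itemset(self.lhs)}}} -> {{{_format_itemset(self.rhs)}}}"


def _sort_rules(rules: list[SequentialRule]) -> list[SequentialRule]:
    # deterministic output order: best rules first, lexicographic tiebreak
    return sorted(rules, key=lambda r: (-r.seq_conf, -r.seq_sup, r.key()))


@dataclass
class RuleSet:
    """Rules mined from one group/dataset.  Biological scores are
    corpus-relative within a rule set, so the set is the scoring unit."""

    group: str
    rules: list[SequentialRule] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def sorted(self) -> "RuleSet":
        return RuleSet(self.group, _sort_rules(list(self.rules)))


_RULE_COLUMNS = [
    "group", "lhs", "rhs", "sup_count", "sup_lhs", "sup_rhs", "n_seq",
    "n_neither", "seq_sup", "seq_conf", "lift", "cf", "conviction",
    *BIO_FIELDS,
]


def _fmt_value(x: float | None) -> str:
    if x is None:
        return ""
    if math.isinf(x):
        return "Inf" if x > 0 else "-Inf"
    return repr(float(x))


def _parse_value(s: str) -> float | None:
    s = s.strip()
    if s == "":
        return None
    if s == "Inf":
        return math.inf
    if s == "-Inf":
        return -math.inf
    return float(s)


def _rule_record(group: str, rule: SequentialRule) -> dict[str, str]:
    m = rule.metrics
    rec = {
        "group": group,
        "lhs": _format_itemset(rule.lhs),
        "rhs": _format_itemset(rule.rhs),
        "sup_count": str(rule.sup_seq),
        "sup_lhs": str(rule.sup_lhs),
        "sup_rhs": str(rule.sup_rhs),
        "n_seq": str(rule.n_sequences),
        "n_neither": "" if rule.n_neither is None else str(rule.n_neither),
        "seq_sup": _fmt_value(m.seq_sup),
        "seq_conf": _fmt_value(m.seq_conf),
        "lift": _fmt_value(m.lift),
        "cf": _fmt_value(m.cf),
        "conviction": _fmt_value(m.conviction),
    }
    for name in BIO_FIELDS:
        rec[name] = _fmt_value(rule.bio.get(name))
    return rec


def _record_rule(rec: Mapping[str, str]) -> tuple[str, SequentialRule]:
    bio = {}
    for name in BIO_FIELDS:
        v = _parse_value(rec.get(name, "") or "")
        if v is not None:
            bio[name] = v
    n_neither = rec.get("n_neither", "")
    rule = SequentialRule(
        lhs=_parse_itemset(rec["lhs"]),
        rhs=_parse_itemset(rec["rhs"]),
        sup_seq=int(rec["sup_count"]),
        sup_lhs=int(rec["sup_lhs"]),
        sup_rhs=int(rec["sup_rhs"]),
        n_sequences=int(rec["n_seq"]),
        n_neither=int(n_neither) if str(n_neither).strip() != "" else None,
        bio=bio,
    )
    return rec["group"], rule


def write_rules(ruleset: RuleSet, path, format: str = "tsv") -> None:
    """Serialize a rule set; ``format`` is ``tsv`` or ``jsonl``.  Writing then
    reading is the identity on every rule field (conviction ``Inf``
    included)."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_RULE_COLUMNS) + "\n")
            for rule in ruleset:
                rec = _rule_record(ruleset.group, rule)
                fh.write("\t".join(rec[c] for c in _RULE_COLUMNS) + "\n")
    elif format == "jsonl":
        with open(path, "w") as fh:
            for rule in ruleset:
                fh.write(json.dumps(_rule_record(ruleset.group, rule)) + "\n")
    else:
        raise ValueError(f"unknown rule format {format!r}")


def read_rules(path, format: str = "tsv") -> RuleSet:
    groups: list[str] = []
    rules: list[SequentialRule] = []
    with open(path) as fh:
        if format == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                rec = dict(zip(header, line.rstrip("\n").split("\t")))
                g, rule = _record_rule(rec)
                groups.append(g)
                rules.append(rule)
        elif format == "jsonl":
            for line in fh:
                if not line.strip():
                    continue
                g, rule = _record_rule(json.loads(line))
                groups.append(g)
                rules.append(rule)
        else:
            raise ValueError(f"unknown rule format {format!r}")
    group = groups[0] if groups else ""
    if any(g != group for g in groups):
        warnings.warn("rule file mixes groups; keeping first group label")
    return RuleSet(group=group, rules=rules)
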