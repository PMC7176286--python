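"""End-to-end orchestration: preprocess -> sequence DBs -> mining ->
biological scoring -> report/plots, from one structured config.

Outputs are a pure function of (inputs, config): no hidden state, fixed
seeds, deterministic file contents.  Every intermediate is written to the
output directory (DE tables, SPMF databases with their item codebook, rule
tables per group, contrast tables, XML match report, network plots, a run
log recording versions/seed/thresholds, and a copy of the config).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .biomeasures import BiologicalScorer, write_match_report
from .cmrules import filter_very_strong, mine_contrast, mine_sequential_rules
from .data_model import (IntervalSet, read_annotation, read_expression_matrix,
                         read_tf_table, write_rules)
from .preprocess import SLRDiscretizer
from .seqdb import build_codebook, build_sequence_db, write_spmf
from .viz import plot_rule_network

__all__ = ["GroupThresholds", "PipelineConfig", "run_pipeline"]

log = logging.getLogger("seqrules")


@dataclass
class GroupThresholds:
    min_seq_sup: float = 0.5
    min_seq_conf: float = 0.6


@dataclass
class PipelineConfig:
    matrix: str = ""
    samples: str = ""
    probe_map: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)  # ns -> path
    tf_table: str | None = None
    alpha: float = 0.05
    lfc: float = 1.0
    de_method: str = "ttest"
    thresholds: dict[str, GroupThresholds] = field(default_factory=dict)
    very_strong: str | None = "cf_only"
    not_sup_threshold: float | None = None
    max_itemset_size: int | None = 4
    contrast: bool = True
    ignore_state: bool = False
    color_by: str = "cf"
    plot_format: str = "svg"
    input_scale: str = "log2"
    drop_incomplete: bool = False
    seed: int = 0
    out_dir: str = "seqrules_output"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = {
            g: GroupThresholds(**t) for g, t in raw.pop("thresholds", {}).items()
        }
        cfg = cls(**raw)
        cfg.thresholds = thresholds
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _thresholds_for(config: PipelineConfig, group: str) -> GroupThresholds:
    return config.thresholds.get(group, GroupThresholds())


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    config.to_yaml(out / "config.yaml")
    log.info("seqrules %s (python %s), seed %d", __version__,
             sys.version.split()[0], config.seed)

    dataset = read_expression_matrix(
        config.matrix, config.samples, probe_map_path=config.probe_map,
        drop_incomplete=config.drop_incomplete, input_scale=config.input_scale)
    unknown = set(config.thresholds) - set(dataset.group_names)
    if unknown:
        raise ValueError(f"config names unknown group(s): {sorted(unknown)}")
    groups = list(config.thresholds) or dataset.group_names
    log.info("dataset: %d subjects, %d probes, timepoints %s, groups %s",
             len(dataset.subjects), len(dataset.probes), dataset.timepoints,
             groups)

    intervals = IntervalSet.consecutive(dataset.timepoints, add_overall=True)
    disc = SLRDiscretizer(intervals=intervals, alpha=config.alpha,
                          lfc=config.lfc, groups=groups,
                          method=config.de_method)
    discrete = disc.fit(dataset).transform(dataset)
    for (label, group), table in disc.de_.tables.items():
        table.to_csv(out / f"de_{group}_{label}.tsv", sep="\t")
    log.info("feature selection: %d probe(s) selected in any interval/group",
             len(disc.de_.selected_probes()))

    codebook = build_codebook(discrete)
    codebook.write(out / "item_codebook.tsv")

    scorer = None
    annotations = {ns: read_annotation(p, ns)
                   for ns, p in config.annotations.items()}
    tf_table = read_tf_table(config.tf_table) if config.tf_table else None
    if annotations or tf_table:
        scorer = BiologicalScorer(annotations=annotations, tf_table=tf_table)

    seqdbs = {}
    rulesets = {}
    for group in groups:
        seqdb = build_sequence_db(discrete[group], group, codebook=codebook)
        seqdbs[group] = seqdb
        write_spmf(seqdb, out / f"sequences_{group}.spmf.txt")
        th = _thresholds_for(config, group)
        rules = mine_sequential_rules(
            seqdb, th.min_seq_sup, th.min_seq_conf,
            max_itemset_size=config.max_itemset_size)
        log.info("group %s: |SD|=%d, %d rule(s) at sup>=%.2f conf>=%.2f",
                 group, len(seqdb), len(rules), th.min_seq_sup,
                 th.min_seq_conf)
        if config.very_strong:
            rules = filter_very_strong(
                rules, th.min_seq_sup, variant=config.very_strong,
                not_sup_threshold=config.not_sup_threshold)
            log.info("group %s: %d very-strong rule(s) [%s]", group,
                     len(rules), config.very_strong)
        if scorer is not None and len(rules):
            rules = scorer.fit(rules).transform(rules)
        rulesets[group] = rules
        write_rules(rules, out / f"rules_{group}.tsv", format="tsv")
        if len(rules):
            plot_rule_network(rules, out / f"network_{group}.{config.plot_format}",
                              color_by=config.color_by, seed=config.seed)
            if annotations:
                write_match_report(rules, annotations,
                                   out / f"matches_{group}.xml")

    if config.contrast and len(groups) == 2:
        a, b = groups
        th_a, th_b = _thresholds_for(config, a), _thresholds_for(config, b)
        # contrast uses each group's own thresholds for mining, the other
        # group's for the exclusivity check when they differ
        only_a, only_b = mine_contrast(
            seqdbs[a], seqdbs[b],
            min_seq_sup=min(th_a.min_seq_sup, th_b.min_seq_sup),
            min_seq_conf=min(th_a.min_seq_conf, th_b.min_seq_conf),
            max_itemset_size=config.max_itemset_size)
        write_rules(only_a, out / f"contrast_only_{a}.tsv")
        write_rules(only_b, out / f"contrast_only_{b}.tsv")
        log.info("contrast: %d rule(s) only in %s, %d only in %s",
                 len(only_a), a, len(only_b), b)

    summary = {
        "groups": {g: len(rulesets[g]) for g in groups},
        "seed": config.seed,
        "version": __version__,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return out
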