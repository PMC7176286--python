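# seqrules

Sequential rule mining and biological scoring for longitudinal
gene-expression data.

## The problem

Long-term human interventions (dietary programs, clinical trials) routinely
collect transcriptome profiles from the same subjects at three or more
timepoints. The question biologists actually ask of such data is temporal
and causal-flavored: *which gene-expression changes during one period are
reliably followed by which changes in a later period, in many subjects, and
do the implicated genes make biological sense together?* Co-expression
clustering answers none of that interpretably. `seqrules` implements a
rule-based, fully inspectable alternative: it turns each subject into an
ordered sequence of discrete gene-change events and mines sequential rules

```
{geneA ↑, geneB ↓}  →(time delay)→  {geneC ↑}
```

that hold across subjects, quantifies each rule with five frequentist
metrics, and then scores each rule against external biological knowledge
(GO terms, pathways, transcription-factor→target tables) so that
statistically strong but biologically incoherent rules can be recognized
and discarded.

## Method at a glance

1. **Feature selection.** For every time interval and intervention group,
   the signal log ratio SLRᵢₖⱼ (log2 change of probe *i* over interval *k*
   in subject *j*) is tested against 0 with a paired t-test; probes with
   Bonferroni-adjusted *p* < 0.05 and |mean SLR| ≥ 1 are kept.
2. **Discretization.** Each selected probe/subject/interval becomes a
   discrete state: 2 ("increase") when SLRᵢₖⱼ exceeds the group mean
   SLRᵢₖⱼ̄ for a positive-DE probe, 1 ("decrease") when it falls below the
   group mean for a negative-DE probe, 0 otherwise.
3. **Sequence databases.** Each subject is one sequence of itemsets (one
   itemset per interval); events are integer-coded `state·10ʷ + probe_index`
   and stored in the standard SPMF text format.
4. **Mining.** A two-phase CMRules-style miner: Apriori over the flattened
   sequences generates candidates (sound, because association support and
   confidence upper-bound their sequential counterparts), then exact
   sequential counting keeps rules with seqSup = sup(LHS→RHS)/|SD| and
   seqConf = sup(LHS→RHS)/sup(LHS) above the thresholds. Each rule carries
   lift, conviction and certainty factor, a very-strong filter
   (seqSup > minSeqSup and CF > 0, with stricter variants available),
   group-contrast mining (rules exclusive to one arm), and gene-level
   replication matching across datasets.
5. **Biological scoring.** Per rule: BP/MF/CC/SP ranking scores in (1, 6]
   (lower = the rule's LHS and RHS genes share annotation terms more
   completely) and a TF score in {0,1,2,3} (LHS gene is a known TF; its
   listed target is on the RHS; the up/down states match the annotated
   regulation mode).
6. **Visualization.** Circular bundled-edge network plots with edge width ←
   seqConf, color ← CF, edge style ← TF support.

## Worked example

Everything is testable without downloads via the synthetic cohort generator,
which plants time-lagged regulation events with known carriers:

```python
from seqrules import (SLRDiscretizer, SequentialRuleMiner, BiologicalScorer,
                      build_sequence_db, filter_very_strong)
from seqrules.seqdb import build_codebook
from seqrules.synthetic import default_cohort, simulate_dataset, simulate_annotations

cfg = default_cohort(seed=1, n_planted=3)          # 2 arms x 24 subjects x 3 timepoints
dataset, truth = simulate_dataset(cfg)
annotations, tf_table = simulate_annotations(truth, seed=1)

discrete = SLRDiscretizer().fit(dataset).transform(dataset)
codebook = build_codebook(discrete)
db = build_sequence_db(discrete["VLCD"], "VLCD", codebook=codebook)

miner = SequentialRuleMiner(min_seq_sup=0.45, min_seq_conf=0.4).fit(db)
rules = filter_very_strong(miner.rules_, 0.45)
rules = BiologicalScorer(annotations=annotations, tf_table=tf_table).transform(rules)
```

Output for the rules above:

```
|SD| = 24, rules mined = 3
{p0001/GLHS00=2} -> {p0002/GRHS00=1}  supN=14 seqSup=0.583 seqConf=1.00 lift=1.71 cf=1.00 conv=inf BP=1.33 TF=3
{p0003/GLHS01=1} -> {p0004/GRHS01=2}  supN=14 seqSup=0.583 seqConf=1.00 lift=1.71 cf=1.00 conv=inf BP=1.33 TF=3
{p0005/GLHS02=2} -> {p0006/GRHS02=2}  supN=14 seqSup=0.583 seqConf=1.00 lift=1.71 cf=1.00 conv=inf BP=1.33 TF=3
```

Reading the first line: probe p0001 of gene GLHS00 going *up* in the first
interval is followed by p0002/GRHS00 going *down* in the second interval in
14 of the 24 subjects (seqSup 0.583) — exactly the planted carriers — and in
*every* sequence that contains the LHS event (seqConf 1.0, hence infinite
conviction). CF = 1 marks maximal positive dependence. BP = 1.33 is a
category-1 annotation score (all rule genes share a GO term); TF = 3 means
the LHS gene is a known TF, the RHS gene is its listed target, and the
up/down directions match the annotated regulation mode.

The same stages are available from the shell:

```bash
seqrule-ged simulate  --out-dir cohort --seed 1
seqrule-ged preprocess --matrix cohort/matrix.tsv --samples cohort/samples.tsv \
                       --probe-map cohort/probe_map.tsv --out-dir work
seqrule-ged mine      --spmf work/sequences_VLCD.spmf.txt \
                      --codebook work/item_codebook.tsv \
                      --min-seq-sup 0.45 --min-seq-conf 0.4 --group VLCD \
                      --out rules.tsv
seqrule-ged annotate  --rules rules.tsv --go-bp cohort/bp.gmt \
                      --tf cohort/tf_table.tsv --out scored.tsv
seqrule-ged plot      --rules scored.tsv --out network.svg
seqrule-ged run       --config pipeline.yaml     # all-in-one
```

## Acceptance script

`scripts/acceptance.py` first exercises the full pipeline end-to-end on the
stock synthetic cohort (generation → feature selection → discretization →
mining → TF scoring) and then recomputes, from scratch with the package's
own scoring code, the three analytic TF-measure cases (full
TF→target→direction cascade; TF and target but unknown mode; TF without a
listed target):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `seqrules.data_model` — typed containers + readers/writers (expression
  TSV + sample sheet, GMT/TSV annotations, TF tables, rule TSV/JSONL).
- `seqrules.preprocess` — SLR computation, DE selection, discretization
  (`SLRDiscretizer`).
- `seqrules.seqdb` — item codes, sequence databases, SPMF I/O.
- `seqrules.cmrules` — the miner (`SequentialRuleMiner`), very-strong
  filter, contrast mining, replication matching.
- `seqrules.biomeasures` — annotation/TF scoring (`BiologicalScorer`),
  XML match report.
- `seqrules.viz` — circular network plots.
- `seqrules.synthetic` — planted-truth cohort generator.
- `seqrules.pipeline` / `seqrules.cli` — orchestration and the
  `seqrule-ged` command.

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
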