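# Methods

This note documents the statistical model and the concrete numerical
choices behind `seqrules`, in the spirit of a package methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and assumptions

Input is a probes × samples matrix of expression values assumed already
normalized on the log2 scale (RMA or equivalent upstream; a
`input_scale: linear` flag applies log2 on load), plus a sample sheet
mapping each column to (subject, timepoint, group). Subjects must have a
complete timepoint series; incomplete subjects are a hard error by default
and are dropped with a warning under `drop_incomplete` (complete-case
analysis). Timepoints are ordinal only — interval lengths play no role.

Time intervals are declared explicitly. Consecutive intervals (T1→T2,
T2→T3, …) are the *mining* intervals; an overall end-vs-baseline interval
may be added flagged `selection_only`: it participates in feature selection
(union rule below) but not in sequence building, because it overlaps the
consecutive intervals and would double-count events.

## Feature selection

For probe *i*, interval *k*, subject *j*, the signal log ratio is
SLRᵢₖⱼ = x(end) − x(start) on the log2 scale, so +1 is a doubling and −1 a
halving. Per (interval, group) family, a one-sample two-sided t-test of
the group's SLRs against 0 (the paired test on endpoint differences) is
Bonferroni-corrected with m = number of probes (each interval × group is
its own family). A probe is selected when p_adj < α (default 0.05) **and**
|mean SLR| ≥ the fold-change threshold (default 1.0, inclusive). A probe
enters downstream analysis if selected in *any* interval/group (union).

The "Bayesian correction" variant is implemented as an empirical-Bayes
moderated t: per-probe variances are shrunk toward the grand mean variance
with `prior_df` (default 4) prior degrees of freedom,
s²_post = (d₀·s̄² + (n−1)·s²)/(d₀ + n − 1), t = mean/√(s²_post/n) on
d₀ + n − 1 df. The plain t-test is the default because it is exactly
reproducible without auxiliary modeling choices; both are exposed
(`method="ttest" | "moderated"`).

Degenerate inputs: zero-variance nonzero differences get t = ±∞, p = 0 by
convention (flagged by the infinite t); an all-zero difference stays
t = 0, p = 1 and is never selected.

## Discretization

Selected probes are mapped, per subject and interval, to three states —
2 "increase", 1 "decrease", 0 "no change" — by comparing the subject's SLR
to the group-mean SLR of that probe and interval:

* positive-DE probe: state 2 iff SLRᵢₖⱼ > mean SLRᵢₖ (strict), else 0;
* negative-DE probe: state 1 iff SLRᵢₖⱼ < mean SLRᵢₖ (strict), else 0;
* non-selected probes: always 0.

Strict inequality means a subject exactly at the group mean is "no
change"; in particular, if all subjects have identical SLRs, nobody gets
an event. Using the group mean as threshold deliberately keys the events
to cohort-level trends rather than individual fluctuation.

## Sequence databases and item encoding

Each subject is one sequence: an ordered list of itemsets, one per mining
interval, containing the integer-coded nonzero states. The code is
`state·10ʷ + probe_index` with w = 4 by default (auto-widened with a
warning), first digit 2 = up, 1 = down; no-change events are simply absent.
Probe indices come from one lexicographic sort shared across groups and are
persisted in a sidecar TSV so codes are reproducible and contrast-
comparable. Empty itemsets are retained — they preserve event positions
and keep |SD| (the support denominator) honest. The on-disk format is the
SPMF dialect (`-1` ends an itemset, `-2` a sequence; an empty itemset is a
bare `-1`).

## The miner

A sequence supports LHS → RHS when some cut position k exists such that
all LHS items occur within itemsets 1..k and all RHS items within
k+1..n — items within one side are unordered, and a single-itemset
sequence can never support a rule. With

* sup(LHS→RHS) = sequences supporting the rule in order,
* sup(LHS), sup(RHS) = sequences containing the itemset anywhere,

the metrics are seqSup = sup(LHS→RHS)/|SD|, seqConf =
sup(LHS→RHS)/sup(LHS), and the sequential analogues of lift
(seqSup/((sup(LHS)/n)(sup(RHS)/n))), conviction
((1 − sup(RHS)/n)/(1 − seqConf), +∞ at seqConf = 1 including the 0/0
corner: perfect implication), and certainty factor (the three-case form
with seqConf in place of confidence and sup(RHS)/n in place of the RHS
support; 0 at equality). These substitutions are the package's design: the
sequential extensions are named but not written out formula-by-formula in
the source methodology, and this choice preserves every domain and sign
identity (cf ∈ [−1,1], sign(cf) = sign(lift − 1)), which the test suite
asserts.

Mining is two-phase. Phase 1 runs levelwise Apriori on the flattened
sequences with min support = minSeqSup and splits each frequent itemset
into candidate (LHS, RHS) pairs at association confidence ≥ minSeqConf.
This pruning is sound because flattened association support ≥ sequential
support and association confidence ≥ sequential confidence (sup(LHS) is
the same count in both). Phase 2 computes exact sequential counts per
candidate and keeps rules meeting both thresholds **inclusively** (≥).
Correctness is verified against a brute-force cut-point enumerator on 200
random databases in the test suite. A `max_itemset_size` cap (default 4)
bounds the lattice; LHS and RHS are disjoint item sets, so the same gene
may sit on both sides only via different items (state or probe), which is
what lets feedback-loop rules appear.

Output ordering is deterministic: descending (seqConf, seqSup), then
lexicographic itemset strings.

### Very-strong filter

The default `cf_only` variant keeps rules with seqSup > minSeqSup and
CF > 0. The textual counter-reciprocal condition — fraction of sequences
containing *neither* side > (1 − minSeqSup) — is implemented as the
`literal` variant, but note it is arithmetically unsatisfiable when
minSeqSup < 0.5 (seqSup > minSeqSup already forces the neither-fraction
below 1 − minSeqSup); `counter_reciprocal` takes a user-chosen threshold
instead. This ambiguity is why `cf_only` is the default.

### Contrast and replication

Contrast mining reports rules passing both thresholds in one group while
failing at least one in the other (exact counts recomputed in the other
group's database; shared item codebooks are required). Replication
matching across datasets compares gene(+state) signatures after dropping
probe identifiers; `ignore_state` also drops the direction, catching
down→down patterns replicated as up→up.

## Biological quality measures

For BP/MF/CC (GO namespaces) and SP (pathways), only *cross terms* count:
terms annotating at least one LHS gene and at least one RHS gene
(probe-level duplicates of a gene are collapsed first). With f_best the
largest fraction of the rule's distinct genes covered by a single cross
term, the category is 1 (f_best = 1), 2 (≥ 0.75), 3 (≥ 0.5), 4 (any cross
match below 0.5) or 5 (none), and the points NP are the total covered
genes summed over cross terms. The ranking score is

    score(r) = CAT(r) + (1 − NP(r) / (maxNP_in_CAT(r) + 1))

with maxNP taken within the rule's category **over the rule set being
scored** (corpus-relative; scoring the same rule in a different set can
give a different score, by design). Scores lie in (1, 6], lower is better,
and a category-5 rule with no matches scores exactly 6. The category bands
and the covered-gene weighting are configurable: the upstream description
fixes the intent (complete term sharing across the rule beats many partial
matches) but not the exact bands, so they are explicit parameters with the
defaults above.

The TF measure is the highest milestone over all (LHS gene, RHS gene)
pairs: 1 if some LHS gene is a listed TF; 2 if additionally some RHS gene
is that TF's listed target; 3 if additionally the regulation mode matches
the discrete directions — Activation requires equal states, Repression
opposite states, Unknown never direction-matches. Duplicate TF rows merge
with informative modes beating Unknown; conflicting Activation/Repression
rows are both kept, so a direction match succeeds if either matches.

An XML report details every cross-term match (term + covered genes) per
rule, alongside the rule metrics.

## Visualization

Nodes are distinct items on a circle grouped by gene; each rule draws one
edge per (LHS item, RHS item) pair as a quadratic Bézier pulled toward the
center (bundling strength configurable) — a deliberate approximation of
hierarchical edge bundling, which prescribes no unique algorithm. Width is
an affine increasing function of seqConf, color maps a chosen metric
(CF by default), solid vs dashed encodes TF ≥ 1. The layout is a pure
function of the rule set; the seed only feeds the SVG hash salt, and
timestamp metadata is stripped, so identical input yields byte-identical
SVG/PDF output.

## Synthetic cohorts

The generator emulates a two-arm longitudinal microarray study: per-subject
baselines ~ N(7, 1) on log2, i.i.d. N(0, 0.2) noise per measurement, 24
subjects per arm, 3 timepoints, 200 probes by default. A planted rule
shifts the LHS gene from timepoint 2 onward and the RHS gene from
timepoint 3 onward (each change therefore lands in exactly one interval)
in a deterministic round(penetrance·N)-subject subset per targeted arm,
drawn by seeded shuffle and returned as exact ground truth. Matching
annotation/TF tables give each planted pair a dedicated shared term per
namespace and a TF row whose mode is consistent with the planted
directions; decoy terms and rows touch only non-planted genes.

Default effect size is 2.5 log2 units. The constraint is that a planted
gene must clear the |mean SLR| ≥ 1 selection gate after penetrance
dilution: the gate sees penetrance·effect with a standard error of
noise_sd·√(2/n) ≈ 0.06, and with ~20 such gates active per cohort the
margin must be several σ for recovery to be seed-robust. 2.5 gives
0.6·2.5 = 1.5 (≈ 8σ above the gate) while weak plants at penetrance 0.2
sit at 0.52 (≈ 8σ below), making both the positive and negative recovery
checks effectively deterministic. An earlier choice of 2.0 left only a
~3σ margin, which a few percent of seeds violate — a miscalibrated
constraint rather than a tolerance issue.

What the generator does **not** model: probe-level affinity effects, batch
structure, within-subject correlation beyond the shared baseline,
heavy-tailed noise, or partially overlapping gene sets between planted
rules. A green recovery test therefore establishes the pipeline's
correctness (selection → discretization → counting arithmetic, exactly
cross-checked against the planted carriers), not robustness to real
microarray artifacts.

## Rule persistence

Rules round-trip losslessly through TSV or JSON-lines with itemsets
serialized as `probe/GENE=state` joined by `&` and infinite conviction as
the literal `Inf`. The raw counts (sup_count, sup_lhs, sup_rhs, n_seq,
n_neither) are stored explicitly — the derived metrics alone cannot
recover them exactly from floats.

## Known limitations

* The miner enumerates candidate rules from the frequent-itemset lattice;
  with very low thresholds and many correlated items the candidate set
  grows combinatorially — `max_itemset_size` (default 4) is the guard, and
  truncation is logged.
* Sequential analogues of lift/conviction/CF are one reasonable extension
  choice; other definitions (e.g. conditioning on LHS-first occurrence
  position) would differ.
* Annotation scoring uses exact term identity only; no GO-graph semantic
  similarity (deliberately out of scope).
* The moderated t is a simple shrinkage estimator, not a full limma
  equivalent.
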