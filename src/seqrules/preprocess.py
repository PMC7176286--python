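"""Feature selection and three-state discretization of expression changes.

The unit of analysis is the signal log ratio (SLR): the within-subject
difference in log2 expression between the two endpoints of a time interval,
so an SLR of +1 is a two-fold increase and -1 a two-fold reduction.

Per group and interval, a probe is selected as differentially expressed when
a one-sample paired t-test of its subjects' SLRs against 0 gives a
Bonferroni-adjusted p below ``alpha`` AND the group-mean SLR is at least
``lfc`` in magnitude (>= 1 by default, i.e. an average two-fold change; the
bound is inclusive).  Selected probes are then discretized per subject by
comparing the subject's SLR to the group-mean SLR:

* positive-DE probe: state 2 ("increase") iff subject SLR > group mean,
* negative-DE probe: state 1 ("decrease") iff subject SLR < group mean,
* otherwise (and for all non-selected probes): state 0 ("no change").

Both comparisons are strict, so a subject sitting exactly at the group mean
is "no change".  Using the group mean as the threshold focuses the discrete
events on cohort-level trends rather than individual idiosyncrasy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import ExpressionDataset, IntervalSet

__all__ = [
    "SLRMatrix",
    "DEResult",
    "DiscreteMatrix",
    "compute_slr",
    "select_de_probes",
    "discretize",
    "SLRDiscretizer",
]


@dataclass
class SLRMatrix:
    """Signal log ratios per (subject, probe, interval).

    ``slr[label]`` is a probes x subjects DataFrame for one interval;
    ``groups`` carries the subject -> group map so group means can be taken
    exactly as the arithmetic mean of the group's subject columns.
    """

    slr: dict[str, pd.DataFrame]
    groups: dict[str, str]
    intervals: IntervalSet

    @property
    def interval_labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]

    def subjects_in_group(self, group: str) -> list[str]:
        out = [s for s, g in self.groups.items() if g == group]
        if not out:
            raise KeyError(f"no subjects in group {group!r}")
        return out

    def group_values(self, interval: str, group: str) -> pd.DataFrame:
        return self.slr[interval][self.subjects_in_group(group)]

    def group_mean(self, interval: str, group: str) -> pd.Series:
        return self.group_values(interval, group).mean(axis=1)


@dataclass
class DEResult:
    """Differential-expression outcome per (probe, interval, group).

    ``tables[(interval, group)]`` has columns ``mean_slr, t, p_raw, p_adj,
    selected, de_sign`` indexed by probe.  ``selected`` iff
    ``p_adj < alpha`` and ``|mean_slr| >= lfc``; ``de_sign`` is the sign of
    ``mean_slr`` when selected, else 0.
    """

    tables: dict[tuple[str, str], pd.DataFrame]
    alpha: float
    lfc: float

    def table(self, interval: str, group: str) -> pd.DataFrame:
        return self.tables[(interval, group)]

    def selected_probes(self, group: str | None = None) -> list[str]:
        """Probes selected in ANY interval (optionally restricted to one
        group) — the union rule by which probes enter downstream analysis."""
        chosen: dict[str, None] = {}
        for (_iv, g), tab in self.tables.items():
            if group is not None and g != group:
                continue
            for probe in tab.index[tab["selected"]]:
                chosen.setdefault(probe, None)
        return list(chosen)


@dataclass
class DiscreteMatrix:
    """Discrete change states in {0, 1, 2} per (subject, probe, interval,
    group); ``states[(interval, group)]`` is probes x subjects, int8."""

    states: dict[tuple[str, str], pd.DataFrame]
    groups: dict[str, str]
    intervals: IntervalSet
    probe_genes: dict[str, str | None] = field(default_factory=dict)

    def table(self, interval: str, group: str) -> pd.DataFrame:
        return self.states[(interval, group)]

    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for (_iv, g) in self.states:
            seen.setdefault(g, None)
        return list(seen)


def compute_slr(dataset: ExpressionDataset, intervals: IntervalSet) -> SLRMatrix:
    """SLR(subject, probe, interval) = log2 value at interval end minus at
    interval start."""
    intervals.validate_against(dataset.timepoints)
    slr: dict[str, pd.DataFrame] = {}
    for iv in intervals:
        end = dataset.values.xs(iv.end, level="timepoint", axis=1)
        start = dataset.values.xs(iv.start, level="timepoint", axis=1)
        slr[iv.label] = end - start
    return SLRMatrix(slr=slr, groups=dict(dataset.groups), intervals=intervals)


def _moderated_scale(diffs: np.ndarray, prior_df: float) -> np.ndarray:
    """Per-probe posterior variance after empirical-Bayes shrinkage toward
    the mean per-probe variance (prior variance = mean of sample variances)."""
    s2 = diffs.var(axis=1, ddof=1)
    s2_prior = float(np.nanmean(s2))
    n = diffs.shape[1]
    return (prior_df * s2_prior + (n - 1) * s2) / (prior_df + n - 1)


def select_de_probes(
    slr: SLRMatrix,
    group: str,
    interval: str,
    alpha: float = 0.05,
    lfc: float = 1.0,
    m: int | None = None,
    method: str = "ttest",
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Differential-expression table for one (interval, group) family.

    A two-sided one-sample t-test of the group's SLRs against 0 (the paired
    test on the endpoint differences), Bonferroni-corrected over ``m`` tests
    (default: number of probes).  ``method="moderated"`` shrinks the per-probe
    variance toward the grand mean variance with ``prior_df`` prior degrees
    of freedom before forming t.  Probes whose SLRs have zero variance get
    t = +/-inf and p_raw = 0 by convention (flagged via the infinite t).
    """
    values = slr.group_values(interval, group)
    n = values.shape[1]
    if n < 2:
        raise ValueError(f"group {group!r} needs >= 2 subjects for a t-test")
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).all(axis=1).any():
        raise ValueError("probe with all-NaN SLRs")
    mean = arr.mean(axis=1)

    if method == "ttest":
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_1samp(arr, 0.0, axis=1)
        df = n - 1
    elif method == "moderated":
        s2_post = _moderated_scale(arr, prior_df)
        df = prior_df + n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(s2_post / n)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        raise ValueError("method must be 'ttest' or 'moderated'")

    # zero-variance probes: t = +/-inf (sign of the mean), p = 0;
    # an all-identical zero difference stays t = 0, p = 1 (never selected).
    zero_var = np.isclose(arr.var(axis=1, ddof=1), 0.0)
    t = np.where(zero_var & (mean != 0), np.copysign(np.inf, mean), t)
    p = np.where(zero_var & (mean != 0), 0.0, p)
    t = np.where(zero_var & (mean == 0), 0.0, t)
    p = np.where(zero_var & (mean == 0), 1.0, p)

    m = len(values.index) if m is None else m
    p_adj = np.minimum(1.0, p * m)
    selected = (p_adj < alpha) & (np.abs(mean) >= lfc)
    de_sign = np.where(selected, np.sign(mean), 0).astype(int)

    return pd.DataFrame(
        {
            "mean_slr": mean,
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
            "selected": selected,
            "de_sign": de_sign,
        },
        index=values.index,
    )


def discretize(slr: SLRMatrix, de: DEResult, group: str) -> DiscreteMatrix:
    """Map each (subject, probe, interval) to a state in {0, 1, 2} for one
    group, using that group's DE signs and group-mean SLRs."""
    states: dict[tuple[str, str], pd.DataFrame] = {}
    for iv in slr.intervals:
        key = (iv.label, group)
        if key not in de.tables:
            raise ValueError(
                f"DE results missing for interval {iv.label!r}, group {group!r}"
            )
        tab = de.tables[key]
        values = slr.group_values(iv.label, group)
        if not tab.index.equals(values.index):
            raise ValueError("DE table and SLR matrix disagree on probes")
        gmean = values.mean(axis=1).to_numpy()[:, None]
        arr = values.to_numpy(dtype=float)
        sign = tab["de_sign"].to_numpy()[:, None]
        out = np.zeros(arr.shape, dtype=np.int8)
        out[(sign > 0) & (arr > gmean)] = 2
        out[(sign < 0) & (arr < gmean)] = 1
        states[key] = pd.DataFrame(out, index=values.index,
                                   columns=values.columns)
    groups = {s: g for s, g in slr.groups.items() if g == group}
    return DiscreteMatrix(states=states, groups=groups, intervals=slr.intervals)


class SLRDiscretizer(BaseEstimator, TransformerMixin):
    """Transformer from an :class:`ExpressionDataset` to a
    :class:`DiscreteMatrix` of per-subject change states.

    ``fit`` computes the SLR matrix and the per-(interval, group) DE tables;
    ``transform`` discretizes every requested group.  The fitted state lives
    in ``slr_``, ``de_``, and ``groups_``.

    Parameters
    ----------
    intervals : IntervalSet or None
        Time intervals to analyze; ``None`` builds consecutive intervals from
        the dataset's timepoints plus a selection-only overall interval.
    alpha, lfc : float
        Bonferroni-adjusted significance level and inclusive absolute
        group-mean SLR threshold for feature selection.
    groups : sequence of str or None
        Groups to process (default: all groups in the dataset).
    method : {"ttest", "moderated"}
        Plain paired t-test, or empirical-Bayes moderated variant.
    prior_df : float
        Prior degrees of freedom for the moderated variant.
    bonferroni_m : int or None
        Number of tests per family; default is the number of probes,
        applied separately per interval and group.
    """

    def __init__(self, intervals: IntervalSet | None = None,
                 alpha: float = 0.05, lfc: float = 1.0,
                 groups=None, method: str = "ttest",
                 prior_df: float = 4.0, bonferroni_m: int | None = None):
        self.intervals = intervals
        self.alpha = alpha
        self.lfc = lfc
        self.groups = groups
        self.method = method
        self.prior_df = prior_df
        self.bonferroni_m = bonferroni_m

    def fit(self, X: ExpressionDataset, y=None) -> "SLRDiscretizer":
        intervals = self.intervals
        if intervals is None:
            intervals = IntervalSet.consecutive(X.timepoints, add_overall=True)
        self.intervals_ = intervals
        self.groups_ = list(self.groups) if self.groups else X.group_names
        unknown = set(self.groups_) - set(X.group_names)
        if unknown:
            raise ValueError(f"unknown group(s): {sorted(unknown)}")
        self.slr_ = compute_slr(X, intervals)
        tables = {}
        for group in self.groups_:
            for iv in intervals:
                tables[(iv.label, group)] = select_de_probes(
                    self.slr_, group, iv.label, alpha=self.alpha,
                    lfc=self.lfc, m=self.bonferroni_m, method=self.method,
                    prior_df=self.prior_df,
                )
        self.de_ = DEResult(tables=tables, alpha=self.alpha, lfc=self.lfc)
        return self

    def transform(self, X: ExpressionDataset) -> dict[str, DiscreteMatrix]:
        if not hasattr(self, "de_"):
            raise ValueError("SLRDiscretizer is not fitted")
        slr = compute_slr(X, self.intervals_)
        out: dict[str, DiscreteMatrix] = {}
        for group in self.groups_:
            dm = discretize(slr, self.de_, group)
            dm.probe_genes = dict(X.probe_genes)
            out[group] = dm
        return out
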