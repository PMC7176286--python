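"""Circular bundled-edge rendering of a rule set.

Every distinct item (probe/gene with an up or down state) is a node on a
circle, nodes grouped by gene; every rule contributes at least one edge from
its LHS to each RHS item, drawn as a quadratic Bezier curve pulled toward
the circle center (a light-weight stand-in for hierarchical edge bundling).
Visual channels, all remappable:

* edge width   <- sequential confidence (monotone, never thinner for higher
  confidence),
* color        <- a chosen metric (certainty factor by default),
* edge style   <- solid when the rule's TF measure is >= 1, dashed otherwise,
* node label   <- "probe/GENE" with an up/down marker.

Rules with a multi-item LHS or RHS are drawn as a hyperedge fan through the
LHS centroid.  Output is deterministic for a fixed seed (the seed feeds the
SVG hash salt; no random layout is used).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import matplotlib
import matplotlib.pyplot as plt
from matplotlib.colors import Normalize
from matplotlib.path import Path as MplPath
import matplotlib.patches as mpatches

from .data_model import RuleItem, RuleSet

__all__ = ["PlotSpec", "EdgeStyle", "build_plot_spec", "plot_rule_network"]

_STATE_MARK = {1: "↓", 2: "↑"}  # down / up arrows


@dataclass(frozen=True)
class EdgeStyle:
    source: RuleItem
    target: RuleItem
    width: float
    color_value: float
    solid: bool
    rule_index: int


@dataclass
class PlotSpec:
    """Resolved layout and style table, testable without rendering pixels."""

    nodes: list[RuleItem]
    positions: dict[RuleItem, tuple[float, float]]
    edges: list[EdgeStyle]
    color_metric: str
    legend: dict[str, str] = field(default_factory=dict)


def _node_label(item: RuleItem) -> str:
    name = f"{item.probe}/{item.gene}" if item.gene else item.probe
    return f"{name} {_STATE_MARK[item.state]}"


def _edge_width(seq_conf: float) -> float:
    return 0.5 + 3.0 * seq_conf  # strictly increasing in confidence


def build_plot_spec(ruleset: RuleSet, color_by: str = "cf") -> PlotSpec:
    """Node order (grouped by gene, then probe/state) and one styled edge
    per (rule, RHS item) pair."""
    if len(ruleset) == 0:
        raise ValueError("nothing to plot: empty rule set")
    items = sorted(
        {i for r in ruleset for i in (r.lhs | r.rhs)},
        key=lambda i: (i.gene or "", i.probe, i.state),
    )
    n = len(items)
    positions = {
        item: (math.cos(2 * math.pi * k / n), math.sin(2 * math.pi * k / n))
        for k, item in enumerate(items)
    }
    edges = []
    for idx, rule in enumerate(ruleset):
        if color_by == "cf":
            color_value = rule.cf
        elif color_by == "lift":
            color_value = rule.lift
        elif color_by == "seq_sup":
            color_value = rule.seq_sup
        elif color_by == "seq_conf":
            color_value = rule.seq_conf
        else:
            raise ValueError(f"unknown color metric {color_by!r}")
        solid = rule.bio.get("tf", 0.0) >= 1.0
        width = _edge_width(rule.seq_conf)
        for source in sorted(rule.lhs):
            for target in sorted(rule.rhs):
                edges.append(EdgeStyle(source=source, target=target,
                                       width=width, color_value=color_value,
                                       solid=solid, rule_index=idx))
    legend = {
        "edge width": "sequential confidence",
        "color intensity": color_by,
        "edge style": "solid = TF measure >= 1",
        "node label": "probe/GENE with direction arrow",
    }
    return PlotSpec(nodes=items, positions=positions, edges=edges,
                    color_metric=color_by, legend=legend)


def _bezier(ax, p0, p1, bundling: float, **kw) -> None:
    # control point pulled toward the center: crude edge bundling
    cx = (p0[0] + p1[0]) / 2 * (1 - bundling)
    cy = (p0[1] + p1[1]) / 2 * (1 - bundling)
    path = MplPath([p0, (cx, cy), p1],
                   [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3])
    ax.add_patch(mpatches.PathPatch(path, fill=False, **kw))


def plot_rule_network(ruleset: RuleSet, path, color_by: str = "cf",
                      bundling: float = 0.75, seed: int = 0,
                      cmap: str = "viridis") -> PlotSpec:
    """Render the rule network to ``path`` (svg, png or pdf) and return the
    :class:`PlotSpec` actually drawn.  Deterministic for a fixed seed."""
    suffix = str(path).rsplit(".", 1)[-1].lower()
    if suffix not in {"svg", "png", "pdf"}:
        raise ValueError(f"unsupported image format {suffix!r}")
    spec = build_plot_spec(ruleset, color_by=color_by)

    with matplotlib.rc_context({"svg.hashsalt": str(seed)}):
        fig, ax = plt.subplots(figsize=(8, 8))
        try:
            values = [e.color_value for e in spec.edges]
            vmin, vmax = min(values), max(values)
            if vmin == vmax:
                vmin, vmax = vmin - 0.5, vmax + 0.5
            norm = Normalize(vmin=vmin, vmax=vmax)
            colormap = plt.get_cmap(cmap)
            for edge in spec.edges:
                _bezier(ax, spec.positions[edge.source],
                        spec.positions[edge.target], bundling,
                        lw=edge.width,
                        color=colormap(norm(edge.color_value)),
                        linestyle="-" if edge.solid else "--")
            for item in spec.nodes:
                x, y = spec.positions[item]
                ax.plot([x], [y], "o", color="#333333", ms=5)
                angle = math.degrees(math.atan2(y, x))
                ha = "left" if -90 <= angle <= 90 else "right"
                rot = angle if -90 <= angle <= 90 else angle + 180
                ax.text(x * 1.06, y * 1.06, _node_label(item), fontsize=7,
                        ha=ha, va="center", rotation=rot,
                        rotation_mode="anchor")
            sm = plt.cm.ScalarMappable(norm=norm, cmap=colormap)
            fig.colorbar(sm, ax=ax, shrink=0.6,
                         label=f"color: {spec.color_metric}")
            legend_lines = [
                plt.Line2D([], [], color="k", lw=2, linestyle="-",
                           label="TF measure >= 1"),
                plt.Line2D([], [], color="k", lw=2, linestyle="--",
                           label="no TF support"),
            ]
            ax.legend(handles=legend_lines, loc="upper left", fontsize=7,
                      title="edge width = seqConf")
            ax.set_xlim(-1.5, 1.5)
            ax.set_ylim(-1.5, 1.5)
            ax.set_aspect("equal")
            ax.axis("off")
            ax.set_title(f"Sequential rules — {ruleset.group}")
            # strip timestamps so identical input gives identical bytes
            if suffix == "svg":
                fig.savefig(path, metadata={"Date": None})
            elif suffix == "pdf":
                fig.savefig(path, metadata={"CreationDate": None})
            else:
                fig.savefig(path)
        finally:
            plt.close(fig)
    return spec
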