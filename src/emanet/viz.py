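"""Network, radar and time-series visualizations.

Conventions: node positions come from the Fruchterman-Reingold layout
averaged (after Procrustes alignment) over the three networks so the same
arrangement serves all panels; weak edges below a display minimum are
hidden (never removed from the model); a cut value separates emphasized
from faint edges; positive edges are drawn blue and negative red; radar
charts put one axis per node and plot raw centralities from zero to a
shared radial maximum.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .metrics import CentralityTable
from .periods import PeriodSpec
from .types import DiaryPanel, NetworkSet

__all__ = [
    "LayoutSpec",
    "average_layout",
    "render_network",
    "render_radar",
    "plot_sample_means",
]

POSITIVE_COLOR = "#2166ac"
NEGATIVE_COLOR = "#b2182b"


@dataclass
class LayoutSpec:
    """2-D node coordinates plus the settings that generated them."""

    coordinates: dict[str, tuple[float, float]]
    algorithm: str
    seed: int
    averaged_over: tuple[str, ...]

    def __post_init__(self) -> None:
        for node, (x, y) in self.coordinates.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinate for node {node}")

    def as_array(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.coordinates[n] for n in nodes])


def _fr_layout(weights: np.ndarray, nodes: list[str], seed: int) -> np.ndarray:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            w = abs(weights[i, j]) + abs(weights[j, i])
            if w > 0:
                g.add_edge(nodes[i], nodes[j], weight=w)
    pos = nx.spring_layout(g, seed=seed)  # Fruchterman-Reingold
    return np.array([pos[n_] for n_ in nodes])


def _procrustes_align(ref: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Rotate/reflect x (after centering) onto ref; translation restored to ref's."""
    ref_c = ref - ref.mean(axis=0)
    x_c = x - x.mean(axis=0)
    R, _ = orthogonal_procrustes(x_c, ref_c)
    return x_c @ R + ref.mean(axis=0)


def average_layout(net: NetworkSet, seed: int = 1) -> LayoutSpec:
    """Average Fruchterman-Reingold layout of the three networks.

    Each network's absolute weights get a seeded force-directed layout;
    layouts are Procrustes-aligned (rotation/reflection) to the first before
    averaging, since force-directed coordinates are only defined up to a
    rigid transform.
    """
    nodes = net.node_labels
    mats = {
        "temporal": net.temporal,
        "contemporaneous": net.contemporaneous,
        "between": net.between,
    }
    layouts = [_fr_layout(m, nodes, seed) for m in mats.values()]
    ref = layouts[0]
    aligned = [ref] + [_procrustes_align(ref, x) for x in layouts[1:]]
    mean = np.mean(aligned, axis=0)
    return LayoutSpec(
        coordinates={n_: (float(x), float(y)) for n_, (x, y) in zip(nodes, mean)},
        algorithm="fruchterman_reingold",
        seed=seed,
        averaged_over=tuple(mats),
    )


def render_network(
    matrix: np.ndarray,
    nodes: list[str],
    layout: LayoutSpec,
    out: str | os.PathLike,
    minimum: float = 0.04,
    cut: float = 0.05,
    maximum: float = 0.4,
    directed: bool | None = None,
    title: str | None = None,
) -> None:
    """Draw one network with the shared display conventions.

    Edges with |w| < ``minimum`` are hidden (inclusive boundary: |w| equal
    to the minimum is drawn); widths scale with |w| relative to ``maximum``,
    with extra emphasis above ``cut``.  Symmetric matrices are drawn without
    arrowheads, asymmetric ones with.  The input matrix is never modified.
    """
    matrix = np.asarray(matrix, dtype=float)
    if directed is None:
        directed = not np.allclose(matrix, matrix.T, atol=1e-10)
    pos = layout.as_array(nodes)
    fig, ax = plt.subplots(figsize=(6, 6))
    n = len(nodes)
    pairs = (
        [(j, k) for j in range(n) for k in range(n) if j != k]
        if directed
        else [(j, k) for j in range(n) for k in range(j + 1, n)]
    )
    for j, k in pairs:
        w = matrix[j, k]
        if abs(w) < minimum:
            continue
        frac = min(abs(w) / maximum, 1.0)
        lw = 0.5 + 4.0 * frac
        alpha = 0.9 if abs(w) >= cut else 0.35
        color = POSITIVE_COLOR if w > 0 else NEGATIVE_COLOR
        # convention: matrix[j, k] is k -> j
        x0, y0 = pos[k]
        x1, y1 = pos[j]
        if directed:
            ax.annotate(
                "",
                xy=(x1, y1),
                xytext=(x0, y0),
                arrowprops=dict(
                    arrowstyle="-|>",
                    color=color,
                    lw=lw,
                    alpha=alpha,
                    shrinkA=12,
                    shrinkB=12,
                    connectionstyle="arc3,rad=0.12",
                ),
            )
        else:
            ax.plot([x0, x1], [y0, y1], color=color, lw=lw, alpha=alpha, zorder=1)
    ax.scatter(pos[:, 0], pos[:, 1], s=700, c="white", edgecolors="black", zorder=2)
    for (x, y), label in zip(pos, nodes):
        ax.annotate(label, (x, y), ha="center", va="center", fontsize=6, zorder=3)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.savefig(out, bbox_inches="tight", dpi=150)
    plt.close(fig)


def render_radar(
    table: CentralityTable,
    panels: list[list[str]],
    out: str | os.PathLike,
) -> None:
    """Radar charts of raw centralities, one panel per metric group.

    ``panels`` is a list of metric-name groups to overlay on one radar
    (e.g. ``[["outstrength", "instrength"]]``).  Axes are the nodes in
    catalog order; overlaid series share one radial scale from 0 to the
    maximum across the group.
    """
    nodes = table.nodes
    if len(nodes) < 3:
        raise ValueError("radar chart needs at least 3 nodes")
    angles = np.linspace(0, 2 * np.pi, len(nodes), endpoint=False)
    fig, axes = plt.subplots(
        1, len(panels), figsize=(5.5 * len(panels), 5.5),
        subplot_kw={"projection": "polar"}, squeeze=False,
    )
    for ax, metrics in zip(axes[0], panels):
        rmax = max(float(table.metric(m).max()) for m in metrics) or 1.0
        for m in metrics:
            vals = table.metric(m).to_numpy()
            closed = np.append(vals, vals[0])
            ang = np.append(angles, angles[0])
            ax.plot(ang, closed, label=m, lw=1.5)
            ax.fill(ang, closed, alpha=0.1)
        ax.set_xticks(angles)
        ax.set_xticklabels(nodes, fontsize=7)
        ax.set_ylim(0, rmax * 1.05)
        ax.set_title(" vs ".join(metrics), fontsize=10)
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=7)
    fig.savefig(out, bbox_inches="tight", dpi=150)
    plt.close(fig)


def plot_sample_means(
    panel: DiaryPanel,
    out: str | os.PathLike,
    period_spec: PeriodSpec | None = None,
) -> None:
    """Daily cross-person mean trajectory per item, one subplot per item.

    Uses raw (pre-detrending) values; a day's mean averages only the persons
    observed that day (no imputation).  Period boundaries, when given, are
    marked with vertical lines.
    """
    items = panel.items
    ncol = min(4, len(items))
    nrow = int(np.ceil(len(items) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.2 * ncol, 2.2 * nrow), squeeze=False, sharex=True
    )
    daily = panel.data.groupby("day")[items].mean()
    for i, it in enumerate(items):
        ax = axes[i // ncol][i % ncol]
        ax.plot(daily.index, daily[it], lw=1.2, color="black")
        if period_spec is not None:
            for name, (lo, hi) in period_spec.intervals.items():
                ax.axvline(lo - 0.5, color="grey", lw=0.6, ls="--")
            ax.axvline(
                max(hi for _, hi in period_spec.intervals.values()) + 0.5,
                color="grey", lw=0.6, ls="--",
            )
        ax.set_title(it, fontsize=8)
    for j in range(len(items), nrow * ncol):
        axes[j // ncol][j % ncol].set_axis_off()
    fig.supxlabel("day")
    fig.supylabel("daily mean")
    fig.tight_layout()
    fig.savefig(out, bbox_inches="tight", dpi=150)
    plt.close(fig)
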