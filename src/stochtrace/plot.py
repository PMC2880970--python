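"""Chart and graph rendering (matplotlib; SVG-friendly)."""

from __future__ import annotations

import colorsys
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .analyze import AnalysisSeries
from .netviz import HslColor, Layout

__all__ = ["plot_series", "render_layout"]


def plot_series(series: Sequence[AnalysisSeries], title: str = "", spread: bool = True):
    """2D chart of analysis series; the optional spread entries become
    variance error bars."""
    fig, ax = plt.subplots(figsize=(8, 5))
    for s in series:
        label = f"{s.species} {s.stat}" + (f" ({s.label})" if s.label else "")
        t, v = s.times, s.values
        ax.plot(t, v, drawstyle="steps-post", label=label, lw=1.0)
        if spread:
            bars = np.array([p[2] if p[2] is not None else np.nan for p in s.points])
            if np.isfinite(bars).any():
                ax.errorbar(
                    t, v, yerr=np.sqrt(np.where(np.isfinite(bars), bars, 0.0)),
                    fmt="none", alpha=0.25, elinewidth=0.5,
                )
    ax.set_xlabel("time")
    ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    if series:
        ax.legend(fontsize=8)
    return fig


def _hsl_to_rgb(c: HslColor) -> tuple[float, float, float]:
    return colorsys.hls_to_rgb(c.hue / 360.0, c.lightness, c.saturation)


def render_layout(
    graph: nx.Graph,
    layout: Layout,
    colors: dict[str, HslColor] | None = None,
    title: str = "",
):
    """Draw a laid-out graph: nodes at their layout positions, directed
    edges, optional per-node fill colors (e.g. centrality tones)."""
    fig, ax = plt.subplots(figsize=(7, 7))
    pos = layout.positions
    for u, v in graph.edges():
        if u in pos and v in pos:
            (x0, y0), (x1, y1) = pos[u], pos[v]
            ax.annotate(
                "",
                xy=(x1, y1),
                xytext=(x0, y0),
                arrowprops=dict(arrowstyle="-|>", color="0.5", lw=0.8),
            )
    for v, (x, y) in pos.items():
        fill = _hsl_to_rgb(colors[v]) if colors and v in colors else (0.7, 0.8, 0.9)
        ax.scatter([x], [y], s=350, color=fill, edgecolors="k", zorder=3)
        ax.text(x, y, str(v), ha="center", va="center", fontsize=7, zorder=4)
    ax.set_xlim(0, layout.canvas.width)
    ax.set_ylim(0, layout.canvas.height)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    return fig
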