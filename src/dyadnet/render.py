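"""Figure rendering for estimated networks (optional, matplotlib).

Conventions: circles for continuous nodes, a square for the dichotomous
child-sex node; green edges for positive partial associations, red for
negative, gray for edges whose bootstrap support falls below 0.5 ("not
significant"); edge width proportional to the absolute weight; node size
scaled by the percent change of the mean score relative to the first
assessment; a ring around each node shades its predictability.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .data_model import NetworkModel
from .graph_structure import LayoutCoordinates


def render_network(
    net: NetworkModel,
    layout: LayoutCoordinates,
    path: str | Path,
    node_sizes: Mapping[str, float] | None = None,
    predictability: Mapping[str, float] | None = None,
    title: str | None = None,
    width_scale: float = 6.0,
) -> Path:
    """Draw one network to ``path`` (format from the suffix); returns the path."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.set_xlim(-0.12, 1.12)
    ax.set_ylim(-0.12, 1.12)
    ax.axis("off")
    for i, j, w in net.edge_list():
        a = layout.coords[net.node_labels[i]]
        b = layout.coords[net.node_labels[j]]
        significant = True
        if net.edge_support is not None:
            significant = bool(net.edge_support[i, j] >= 0.5)
        if not significant:
            color = "0.6"
        elif net.edge_kind(i, j) == "unsigned_mixed":
            color = "0.2"
        else:
            color = "forestgreen" if w > 0 else "firebrick"
        ax.plot(
            [a[0], b[0]], [a[1], b[1]],
            color=color, linewidth=max(0.5, abs(w) * width_scale), zorder=1,
        )
    for k, lab in enumerate(net.node_labels):
        x, y = layout.coords[lab]
        size = (node_sizes or {}).get(lab, 1.0)
        marker = "s" if net.node_types[k] == "categorical" else "o"
        ring = (predictability or {}).get(lab)
        edgecolor = str(1.0 - 0.8 * ring) if ring is not None else "black"
        ax.scatter(
            [x], [y], s=500 * size, marker=marker, zorder=2,
            facecolor="lightsteelblue", edgecolor=edgecolor, linewidths=2.5,
        )
        ax.annotate(lab, (x, y), ha="center", va="center", fontsize=6, zorder=3)
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
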