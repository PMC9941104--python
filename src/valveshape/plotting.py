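"""Matplotlib views of the pipeline's results: wireframes, phylomorphospace."""

from __future__ import annotations

import numpy as np


def _axes(ax=None):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    return ax


def plot_wireframe(shape, edges, ax=None, **line_kw):
    """Draw one landmark configuration as a neighbour-linked wireframe."""
    ax = _axes(ax)
    shape = np.asarray(shape, float).reshape(-1, 2)
    for i, j in edges:
        ax.plot(shape[[i, j], 0], shape[[i, j], 1], **({"color": "k"} | line_kw))
    ax.set_aspect("equal")
    return ax


def plot_pc_extremes(model, pc, magnitude, edges=None, ax=None):
    """Overlay the mean shape and the +/- extreme along one PC."""
    from .pca import pc_extremes

    minus, plus, edges = pc_extremes(model, pc, magnitude, edges=edges)
    ax = _axes(ax)
    plot_wireframe(model.mean, edges, ax=ax, color="0.7")
    plot_wireframe(minus, edges, ax=ax, color="tab:blue", alpha=0.8)
    plot_wireframe(plus, edges, ax=ax, color="tab:red", alpha=0.8)
    ax.set_title(f"PC{pc + 1} extremes (+/- {magnitude:g})")
    return ax


def plot_phylomorphospace(nodes, edges, ax=None, clades=None):
    """Tree projected into a 2-D score space: tips as dots, ancestors as
    small squares, branches as lines (long crisscrossing branches are the
    visual signature of weak phylogenetic signal)."""
    ax = _axes(ax)
    for parent, child in edges:
        seg = nodes.loc[[parent, child]]
        ax.plot(seg["x"], seg["y"], color="0.6", lw=0.8, zorder=1)
    tips = nodes[nodes["is_tip"]]
    internal = nodes[~nodes["is_tip"]]
    if clades:
        colors = {c: f"C{i}" for i, c in enumerate(sorted(set(clades.values())))}
        col = [colors.get(clades.get(t, ""), "k") for t in tips.index]
    else:
        col = "tab:blue"
    ax.scatter(tips["x"], tips["y"], c=col, s=28, zorder=3)
    ax.scatter(internal["x"], internal["y"], marker="s", c="0.3", s=10, zorder=2)
    for label, row in tips.iterrows():
        ax.annotate(str(label), (row["x"], row["y"]), fontsize=6,
                    xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    return ax
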