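"""Minimal figure rendering for the CLI (PNG/PDF via matplotlib Agg).

Figures are intentionally basic: the data exports (CSV/JSON/Newick/FASTA)
are the primary artifacts; each figure gets an optional time-stamp footer.
"""

from __future__ import annotations

import math
from datetime import datetime, timezone

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap

_CLASS_COLOURS = ["#3b6fb6", "#f2c14e", "#c0392b", "#bdbdbd"]  # ref/het/alt/missing


def _stamp(fig, params: str, stamp: bool) -> None:
    if stamp:
        ts = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
        fig.text(0.01, 0.005, f"varscope {ts} {params}", fontsize=6, alpha=0.7)


def save_heatmap(layout, path: str, params: str = "", stamp: bool = True) -> None:
    fig, ax = plt.subplots(figsize=(8, 5))
    cmap = ListedColormap(_CLASS_COLOURS)
    if layout.grid:
        ax.imshow(layout.grid, aspect="auto", cmap=cmap, vmin=0, vmax=3)
    if layout.orientation == "sites_by_rows":
        ax.set_xlabel("samples")
        ax.set_ylabel("sites")
    else:
        ax.set_xlabel("sites")
        ax.set_ylabel("samples")
    _stamp(fig, params, stamp)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_network(network, path: str, params: str = "", stamp: bool = True) -> None:
    nodes = network.nodes
    n = len(nodes)
    coords = {
        h.hap_id: (math.cos(2 * math.pi * i / n), math.sin(2 * math.pi * i / n))
        for i, h in enumerate(nodes)
    }
    fig, ax = plt.subplots(figsize=(6, 6))
    for a, b, w in network.edges:
        (x1, y1), (x2, y2) = coords[a], coords[b]
        ax.plot([x1, x2], [y1, y2], "-", color="#888888", zorder=1)
        ax.text((x1 + x2) / 2, (y1 + y2) / 2, str(w), fontsize=7, color="#555555")
    total = sum(h.size for h in nodes)
    for h in nodes:
        x, y = coords[h.hap_id]
        ax.scatter([x], [y], s=200 + 2000 * h.size / max(total, 1), zorder=2)
        ax.text(x, y, f"{h.hap_id}\n{h.size}", ha="center", va="center", fontsize=7)
    ax.set_axis_off()
    _stamp(fig, params, stamp)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_tree(tree, path: str, params: str = "", stamp: bool = True) -> None:
    """Basic phylogram-style drawing of the unrooted tree."""
    leaf_y = {}
    counter = [0]

    def layout(node, x):
        if node.is_leaf:
            y = counter[0]
            counter[0] += 1
            leaf_y[id(node)] = (x, y, node.name)
            return y
        ys = []
        child_pts = []
        for child, length in node.children:
            cy = layout(child, x + length)
            child_pts.append((x + length, cy))
            ys.append(cy)
        y = sum(ys) / len(ys)
        for cx, cy in child_pts:
            segments.append(((x, y), (x, cy)))
            segments.append(((x, cy), (cx, cy)))
        return y

    segments: list = []
    layout(tree, 0.0)
    fig, ax = plt.subplots(figsize=(7, max(3, 0.3 * counter[0])))
    for (x1, y1), (x2, y2) in segments:
        ax.plot([x1, x2], [y1, y2], "-", color="#333333")
    for x, y, name in leaf_y.values():
        ax.text(x, y, f" {name}", va="center", fontsize=8)
    ax.set_yticks([])
    ax.set_xlabel("distance")
    _stamp(fig, params, stamp)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_mds(labels, coords, path: str, params: str = "", stamp: bool = True) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    xs = coords[:, 0]
    ys = coords[:, 1] if coords.shape[1] > 1 else [0.0] * len(labels)
    ax.scatter(xs, ys)
    for lab, x, y in zip(labels, xs, ys):
        ax.annotate(lab, (x, y), fontsize=7)
    ax.set_xlabel("PCo1")
    ax.set_ylabel("PCo2")
    _stamp(fig, params, stamp)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_lollipop(data: dict, path: str, params: str = "", stamp: bool = True) -> None:
    groups = sorted({g for s in data["sites"] for g in s["stems"]})
    n_tracks = max(len(groups), 1)
    fig, axes = plt.subplots(
        n_tracks + 1, 1, figsize=(8, 2 * n_tracks + 1.5), sharex=True
    )
    axes = list(axes) if n_tracks + 1 > 1 else [axes]
    for ax, group in zip(axes, groups):
        for s in data["sites"]:
            f = s["stems"].get(group)
            if f is None:
                continue
            ax.plot([s["pos"], s["pos"]], [0, f], "-", color="#555555")
            ax.plot([s["pos"]], [f], "o", markersize=4)
        ax.set_ylim(0, 1.05)
        ax.set_ylabel(group, fontsize=8)
    tax = axes[-1]
    for i, t in enumerate(data["transcripts"]):
        y = -i
        for s, e in t["exons"]:
            tax.plot([s, e], [y, y], "-", lw=4, color="#8fb9e0")
        for s, e in t["cds"]:
            tax.plot([s, e], [y, y], "-", lw=7, color="#3b6fb6")
        tax.text(t["exons"][0][0], y + 0.3, f"{t['transcript']} ({t['strand']})",
                 fontsize=7)
    tax.set_yticks([])
    tax.set_xlabel("position")
    _stamp(fig, params, stamp)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_geo(circles, path: str, params: str = "", stamp: bool = True) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    for c in circles:
        ax.scatter([c.longitude], [c.latitude], s=80 + 60 * c.size, alpha=0.6)
        ax.text(c.longitude, c.latitude, str(c.size), ha="center", va="center",
                fontsize=7)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    _stamp(fig, params, stamp)
    fig.savefig(path, dpi=120)
    plt.close(fig)
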