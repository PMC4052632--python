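"""Figure and table export: heatmaps, dendrograms, graph plots, seed montages."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .graph_analysis import Dendrogram, Layout, degree_centrality
from .seed_analysis import StatMap

__all__ = [
    "plot_heatmap_panels",
    "plot_dendrogram",
    "plot_energized_graph",
    "plot_circular_graph",
    "plot_seed_montage",
]


def _heatmap(ax, mat, sig, title, cmap, vlim):
    im = ax.imshow(mat, cmap=cmap, vmin=-vlim, vmax=vlim, interpolation="nearest")
    if sig is not None:
        ii, jj = np.nonzero(sig != 0)
        ax.scatter(jj, ii, s=2, c="white", marker="o", linewidths=0)
    ax.set_title(title, fontsize=9)
    ax.set_xlabel("ROI")
    ax.set_ylabel("ROI")
    return im


def plot_heatmap_panels(z_a, sig_a, z_b, sig_b, zdiff, sig_diff, path, group_names=("A", "B")):
    """Three-panel figure: group A z, group B z, A-vs-B difference Z.

    Significant cells are marked with white dots; positive difference
    means larger r in group A.
    """
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    vlim = np.nanmax(np.abs(np.concatenate([np.ravel(z_a), np.ravel(z_b)])))
    vlim = float(vlim) if np.isfinite(vlim) and vlim > 0 else 1.0
    _heatmap(axes[0], z_a, sig_a, f"{group_names[0]} (Fisher z)", "RdBu_r", vlim)
    _heatmap(axes[1], z_b, sig_b, f"{group_names[1]} (Fisher z)", "RdBu_r", vlim)
    dlim = np.nanmax(np.abs(zdiff))
    dlim = float(dlim) if np.isfinite(dlim) and dlim > 0 else 1.0
    im = _heatmap(
        axes[2], zdiff, sig_diff, f"{group_names[0]} vs {group_names[1]} (diff Z)", "RdBu_r", dlim
    )
    fig.colorbar(im, ax=axes[2], shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dendrogram(dend: Dendrogram, path, cut_k: int | None = None):
    """Horizontal dendrogram; optional vertical cut line for ``cut_k`` clusters."""
    from scipy.cluster import hierarchy

    fig, ax = plt.subplots(figsize=(6, max(3, 0.12 * len(dend.labels))))
    hierarchy.dendrogram(
        dend.linkage_matrix, labels=dend.labels, orientation="left", ax=ax, leaf_font_size=5
    )
    if cut_k is not None and 1 < cut_k <= len(dend.labels):
        heights = dend.heights
        # cut between the merges that leave cut_k clusters
        hi = heights[-(cut_k - 1)]
        lo = heights[-cut_k] if cut_k <= len(heights) else 0.0
        ax.axvline(0.5 * (lo + hi), color="gray", linestyle="--", linewidth=1)
    ax.set_xlabel("dissimilarity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _draw_edges(ax, graph, pos):
    for u, v, data in graph.edges(data=True):
        sign = int(data.get("sign", 1))
        x = [pos[u][0], pos[v][0]]
        y = [pos[u][1], pos[v][1]]
        if sign >= 0:
            ax.plot(x, y, color="red", linestyle="-", linewidth=0.7, zorder=1)
        else:
            ax.plot(x, y, color="blue", linestyle="--", linewidth=0.7, zorder=1)


def _draw_nodes(ax, graph, pos):
    degrees = degree_centrality(graph)
    for u in graph.nodes():
        area = 10.0 + 12.0 * degrees[u]  # node area proportional to degree (+floor)
        ax.scatter(*pos[u], s=area, c="lightgray", edgecolors="black", linewidths=0.5, zorder=2)
        ax.annotate(
            str(graph.nodes[u].get("name", u)),
            pos[u],
            fontsize=4,
            ha="center",
            va="center",
            zorder=3,
        )


def plot_energized_graph(graph: nx.Graph, layout: Layout, path):
    """Force-directed plot: solid red positive edges, dashed blue negative,
    node area proportional to degree centrality."""
    pos = layout.positions()
    fig, ax = plt.subplots(figsize=(6, 6))
    _draw_edges(ax, graph, pos)
    _draw_nodes(ax, graph, pos)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def circular_positions(graph: nx.Graph, bands: list[str]) -> dict:
    """Circle coordinates: dorsal-band nodes on the upper semicircle,
    ventral on the lower, each ordered by anterior→posterior index."""
    nodes = sorted(graph.nodes())
    if len(bands) != len(nodes):
        raise ValueError("bands list must match the node count")
    upper = [u for u in nodes if bands[u] == "dorsal"]
    lower = [u for u in nodes if bands[u] != "dorsal"]
    pos = {}
    for u, frac in zip(upper, np.linspace(0.05, 0.95, max(len(upper), 1))):
        theta = np.pi * (1.0 - frac)  # anterior at the left end of the upper arc
        pos[u] = np.array([np.cos(theta), np.sin(theta)])
    for u, frac in zip(lower, np.linspace(0.05, 0.95, max(len(lower), 1))):
        theta = np.pi * (1.0 + frac)
        pos[u] = np.array([np.cos(theta), np.sin(theta)])
    return pos


def plot_circular_graph(graph: nx.Graph, bands: list[str], path):
    pos = circular_positions(graph, bands)
    fig, ax = plt.subplots(figsize=(6, 6))
    _draw_edges(ax, graph, pos)
    _draw_nodes(ax, graph, pos)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_seed_montage(smap: StatMap, path, n_cols: int = 8):
    """Montage of coronal r-value slices with surviving cluster outlines."""
    n_slices = smap.r.shape[1]
    step = max(1, n_slices // (n_cols * 3))
    slices = list(range(0, n_slices, step))
    n_rows = int(np.ceil(len(slices) / n_cols))
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(1.4 * n_cols, 1.4 * n_rows))
    axes = np.atleast_2d(axes)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, j in zip(axes.ravel(), slices):
        ax.imshow(smap.r[:, j, :].T, cmap="RdBu_r", vmin=-1, vmax=1, origin="lower")
        if smap.cluster_labels is not None:
            lab = smap.cluster_labels[:, j, :].T
            if np.any(lab != 0):
                ax.contour(lab != 0, levels=[0.5], colors="black", linewidths=0.5)
        ax.set_title(f"j={j}", fontsize=5)
    fig.suptitle(f"{smap.group} / seed {smap.seed_name}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
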