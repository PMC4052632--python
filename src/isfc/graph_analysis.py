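"""Signed functional-connectivity graph construction and characterization.

Nodes are ROIs (ordered anterior→posterior as in the layout); an edge
links every pair whose correlation is significant, carrying the sign of
r.  The network is characterized by degree centrality, a
structural-equivalence dissimilarity on signed connection profiles,
average-linkage hierarchical clustering, and a force-directed
(stress-minimizing) layout whose energy decreases monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy

from .fc_stats import FCMatrix

__all__ = [
    "build_fc_graph",
    "degree_centrality",
    "signed_adjacency",
    "d1_dissimilarity_matrix",
    "Dendrogram",
    "hierarchical_clustering",
    "Layout",
    "kamada_kawai_layout",
    "write_pajek",
    "write_graphml",
]


def build_fc_graph(fc: FCMatrix, alpha: float | None = None) -> nx.Graph:
    """Graph with an edge for every significantly correlated ROI pair.

    Edge attributes: ``sign`` (+1/−1) and ``weight`` (the Pearson r).
    Node attributes: ``name`` and 0-based anterior→posterior ``index``.
    Undefined correlations never produce an edge.  ``alpha`` overrides
    the FCMatrix threshold when given.
    """
    k = fc.n_rois
    g = nx.Graph()
    for i, name in enumerate(fc.roi_names):
        g.add_node(i, name=name, index=i)
    if alpha is None:
        sig = fc.sig
    else:
        with np.errstate(invalid="ignore"):
            hit = (fc.p < alpha) & ~np.isnan(fc.r)
        sig = np.zeros_like(fc.sig)
        sig[hit] = np.sign(fc.r[hit]).astype(np.int8)
    for i in range(k):
        for j in range(i + 1, k):
            if sig[i, j] != 0:
                g.add_edge(i, j, sign=int(sig[i, j]), weight=float(fc.r[i, j]))
    return g


def degree_centrality(graph: nx.Graph) -> dict:
    """Number of incident edges per node, sign-agnostic (raw counts)."""
    return {node: int(deg) for node, deg in graph.degree()}


def signed_adjacency(graph: nx.Graph) -> np.ndarray:
    """Signed adjacency matrix L ∈ {−1, 0, +1} in node-index order."""
    nodes = sorted(graph.nodes())
    pos = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=np.int8)
    for u, v, data in graph.edges(data=True):
        s = int(data.get("sign", 1))
        adj[pos[u], pos[v]] = s
        adj[pos[v], pos[u]] = s
    return adj


def d1_dissimilarity_matrix(graph: nx.Graph) -> np.ndarray:
    """Structural-equivalence dissimilarity on signed connection profiles.

    d1(u, v) = |{w ∉ {u, v} : L(u, w) ≠ L(v, w)}| / (n − 2), where L is
    the signed adjacency (absent edge = 0, and a positive vs a negative
    edge to the same third node counts as a difference).  Symmetric,
    zero diagonal, range [0, 1].
    """
    adj = signed_adjacency(graph)
    n = adj.shape[0]
    if n < 3:
        raise ValueError("d1 dissimilarity needs at least 3 nodes")
    diff = (adj[:, None, :] != adj[None, :, :]).sum(axis=2).astype(float)
    # drop comparisons at positions u and v themselves:
    # at w=u the pair contributes (L[u,u]=0 vs L[v,u]) and at w=v
    # (L[u,v] vs L[v,v]=0) — both differ exactly when the (u,v) edge exists.
    diff -= 2.0 * (adj != 0)
    np.fill_diagonal(diff, 0.0)
    return diff / (n - 2)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over ROI nodes.

    ``linkage_matrix`` follows the scipy convention; merge heights are
    in d1 units and non-decreasing from leaves to root (average
    linkage is monotone).
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Partition the leaves into ``k`` flat clusters (labels 1..k)."""
        if not 1 <= k <= len(self.labels):
            raise ValueError(f"k must be in [1, {len(self.labels)}]")
        if self.linkage_matrix.size == 0:  # single leaf
            return np.ones(len(self.labels), dtype=np.int32)
        return hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage_matrix))

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = fmt(tree.left, tree.dist)
        right = fmt(tree.right, tree.dist)
        return f"({left},{right});"


def hierarchical_clustering(
    d1: np.ndarray, labels: list[str] | None = None, method: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a symmetric zero-diagonal dissimilarity."""
    d1 = np.asarray(d1, dtype=float)
    n = d1.shape[0]
    if d1.shape != (n, n):
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d1, d1.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d1), 0.0):
        raise ValueError("dissimilarity must have a zero diagonal")
    if labels is None:
        labels = [f"node{i}" for i in range(n)]
    if n == 1:
        return Dendrogram(linkage_matrix=np.empty((0, 4)), labels=list(labels), method=method)
    condensed = d1[np.triu_indices(n, k=1)]
    linkage_matrix = hierarchy.linkage(condensed, method=method)
    return Dendrogram(linkage_matrix=linkage_matrix, labels=list(labels), method=method)


@dataclass
class Layout:
    """2D force-directed node coordinates with the achieved stress energy."""

    coords: np.ndarray  # (n, 2)
    energy: float
    energies: np.ndarray  # energy after each accepted update (non-increasing)
    nodes: list

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("layout coordinates must be finite")

    def positions(self) -> dict:
        return {u: self.coords[i] for i, u in enumerate(self.nodes)}


def _graph_distances(graph: nx.Graph) -> np.ndarray:
    """Unweighted shortest-path distances, sign-agnostic.

    Disconnected pairs are set to (max finite distance) + 1.
    """
    nodes = sorted(graph.nodes())
    pos = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        for dst, d in lengths.items():
            dist[pos[src], pos[dst]] = d
    finite = dist[np.isfinite(dist)]
    dmax = finite.max() if finite.size else 0.0
    dist[~np.isfinite(dist)] = dmax + 1.0
    return dist


def _stress_energy(coords: np.ndarray, ideal: np.ndarray, weight: np.ndarray) -> float:
    delta = coords[:, None, :] - coords[None, :, :]
    dists = np.sqrt((delta**2).sum(axis=2))
    iu = np.triu_indices(coords.shape[0], k=1)
    return float((weight[iu] * (dists[iu] - ideal[iu]) ** 2).sum())


def kamada_kawai_layout(
    graph: nx.Graph,
    seed: int = 0,
    edge_length: float = 1.0,
    tol: float = 1e-6,
    max_updates: int | None = None,
) -> Layout:
    """Force-directed layout minimizing the Kamada–Kawai stress energy.

    E = Σ_{u<v} (1 / (2 d_uv²)) · (‖p_u − p_v‖ − L·d_uv)² with d_uv the
    sign-agnostic unweighted shortest-path distance and L =
    ``edge_length``.  Starting from a seeded circular arrangement, the
    node with the largest energy gradient is moved by a damped 2D Newton
    step, accepted only if the energy strictly decreases — so the
    recorded energy trajectory is monotonically non-increasing and the
    final energy never exceeds the initial one.
    """
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n == 0:
        raise ValueError("layout needs at least one node")
    if n == 1:
        return Layout(coords=np.zeros((1, 2)), energy=0.0, energies=np.zeros(1), nodes=nodes)
    dist = _graph_distances(graph)
    ideal = edge_length * dist
    with np.errstate(divide="ignore"):
        weight = 1.0 / (2.0 * dist**2)
    np.fill_diagonal(weight, 0.0)

    rng = np.random.default_rng(seed)
    radius = edge_length * max(dist.max(), 1.0) / 2.0
    angles = 2.0 * np.pi * np.arange(n) / n + rng.uniform(0, 2 * np.pi)
    coords = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    coords += rng.normal(0.0, 1e-3 * edge_length, coords.shape)

    def gradients(c):
        delta = c[:, None, :] - c[None, :, :]
        d = np.sqrt((delta**2).sum(axis=2))
        np.fill_diagonal(d, 1.0)  # avoid 0/0; weight diagonal is 0 anyway
        coef = 2.0 * weight * (d - ideal) / d
        np.fill_diagonal(coef, 0.0)
        return (coef[:, :, None] * delta).sum(axis=1)

    energy = _stress_energy(coords, ideal, weight)
    energies = [energy]
    if max_updates is None:
        max_updates = 200 * n
    for _ in range(max_updates):
        grad = gradients(coords)
        norms = np.linalg.norm(grad, axis=1)
        m = int(np.argmax(norms))
        if norms[m] < tol:
            break
        # 2x2 Hessian of E wrt node m's coordinates
        delta = coords[m] - coords
        d = np.linalg.norm(delta, axis=1)
        d[m] = 1.0
        w = weight[m]
        l = ideal[m]
        dx, dy = delta[:, 0], delta[:, 1]
        hxx = (2 * w * (1.0 - l * dy**2 / d**3)).sum()
        hyy = (2 * w * (1.0 - l * dx**2 / d**3)).sum()
        hxy = (2 * w * l * dx * dy / d**3).sum()
        hess = np.array([[hxx, hxy], [hxy, hyy]])
        try:
            step = np.linalg.solve(hess, -grad[m])
        except np.linalg.LinAlgError:
            step = -grad[m]
        moved = False
        for _halving in range(30):
            candidate = coords.copy()
            candidate[m] = coords[m] + step
            cand_energy = _stress_energy(candidate, ideal, weight)
            if cand_energy < energy:
                coords, energy = candidate, cand_energy
                energies.append(energy)
                moved = True
                break
            step = step / 2.0
        if not moved:
            break
    return Layout(coords=coords, energy=energy, energies=np.asarray(energies), nodes=nodes)


def write_pajek(graph: nx.Graph, path) -> None:
    """Pajek NET export (sign and weight as edge values)."""
    g = nx.relabel_nodes(graph, {u: graph.nodes[u].get("name", str(u)) for u in graph.nodes()})
    nx.write_pajek(g, path)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
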