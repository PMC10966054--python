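"""Mapper shape-graph construction.

The algorithm compresses a high-dimensional labeled point cloud into a graph:

1. *Filter*: embed the cloud in 2-D (identity / linear projection /
   nonlinear manifold embedding).  The embedding is only a lens — clustering
   happens in the original feature space.
2. *Cover*: overlapping rectangular bins over the lens image (``b`` divisions
   per dimension, overlap fraction ``p``).
3. *Partial clustering*: density-based clustering of each bin's preimage,
   with a single global epsilon chosen so that every point of the full cloud
   has at least ``k`` neighbors within epsilon.
4. *Graph*: one node per cluster, edges between clusters sharing points.

Noise points of the density clustering are kept as singleton clusters so
that no frame is ever dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csgraph, csr_matrix
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

from .exceptions import DimensionError, ParameterError, ValidationError

__all__ = [
    "FilterEmbedding",
    "Cover",
    "ShapeGraph",
    "fit_filter",
    "build_cover",
    "assign_bins",
    "select_epsilon",
    "cluster_bin",
    "build_graph",
    "expected_points_per_nonempty_bin",
    "mapper_graph",
]

_FILTER_ALIASES = {
    "identity": "identity",
    "linear": "linear",
    "linear-projection": "linear",
    "pca": "linear",
    "manifold": "manifold",
    "nonlinear-manifold": "manifold",
    "umap": "manifold",
}


@dataclass(frozen=True)
class FilterEmbedding:
    """2-D lens image of the input cloud."""

    coords: np.ndarray
    method: str
    seed: int

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def fit_filter(data: np.ndarray, method: str = "linear", seed: int = 0) -> FilterEmbedding:
    """Embed ``data`` (frames x features) in 2-D.

    Methods: ``identity`` (requires 2-D input), ``linear`` (top-2
    variance-maximizing projection, deterministic), ``manifold``
    (UMAP-style neighbor-graph embedding, seeded).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise DimensionError("data must be a frames x features matrix")
    if data.shape[0] < 10:
        raise ValidationError("need at least 10 frames")
    if not np.all(np.isfinite(data)):
        raise ValidationError("data must be finite")
    try:
        method = _FILTER_ALIASES[method]
    except KeyError:
        raise ParameterError(f"unknown filter method {method!r}") from None

    if method == "identity":
        if data.shape[1] != 2:
            raise DimensionError("identity filter requires 2-D input")
        coords = data.copy()
    elif method == "linear":
        centered = data - data.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        coords = u[:, :2] * s[:2]
        # Sign convention: largest-|loading| entry of each axis positive.
        for j in range(coords.shape[1]):
            i = np.argmax(np.abs(vt[j]))
            if vt[j, i] < 0:
                coords[:, j] = -coords[:, j]
        if data.shape[1] < 2:  # rank padding for 1-feature input
            coords = np.column_stack([coords, np.zeros(len(coords))])
    else:  # manifold
        import umap  # deferred: heavy import

        reducer = umap.UMAP(n_components=2, random_state=seed)
        coords = np.asarray(reducer.fit_transform(data), dtype=float)
    return FilterEmbedding(coords=coords, method=method, seed=seed)


@dataclass(frozen=True)
class Cover:
    """Overlapping rectangular cover of a 2-D embedding's bounding box.

    Per dimension: base width ``(max - min) / b``; interval ``i`` is centered
    at ``min + (i + 1/2) * base`` with half-width ``base * (1 + p) / 2``.
    """

    b: int
    p: float
    centers: np.ndarray      # (2, b)
    half_widths: np.ndarray  # (2,)

    def interval_membership(self, x: np.ndarray, dim: int) -> np.ndarray:
        """Boolean (n, b) membership of coordinates in dimension ``dim``."""
        c = self.centers[dim]
        hw = self.half_widths[dim]
        tol = 1e-9 * max(hw, 1.0)
        return np.abs(x[:, None] - c[None, :]) <= hw + tol


def build_cover(embedding: FilterEmbedding, b: int = 30, p: float = 0.5) -> Cover:
    if b < 2:
        raise ParameterError("b must be >= 2")
    if not 0.0 <= p < 1.0:
        raise ParameterError("p must lie in [0, 1)")
    coords = embedding.coords
    mins = coords.min(axis=0)
    maxs = coords.max(axis=0)
    if np.any(maxs - mins <= 0):
        raise ValidationError("degenerate embedding dimension (max == min)")
    base = (maxs - mins) / b
    offsets = (np.arange(b) + 0.5)
    centers = mins[:, None] + offsets[None, :] * base[:, None]
    half_widths = base * (1.0 + p) / 2.0
    return Cover(b=b, p=p, centers=centers, half_widths=half_widths)


def assign_bins(embedding: FilterEmbedding, cover: Cover) -> dict[tuple[int, int], np.ndarray]:
    """Map every 2-D bin ``(i, j)`` to the frame indices it contains.

    Closed intervals per dimension; empty bins are recorded with an empty
    index array.
    """
    mem0 = cover.interval_membership(embedding.coords[:, 0], 0)
    mem1 = cover.interval_membership(embedding.coords[:, 1], 1)
    bins: dict[tuple[int, int], np.ndarray] = {}
    for i in range(cover.b):
        rows = np.flatnonzero(mem0[:, i])
        if rows.size == 0:
            for j in range(cover.b):
                bins[(i, j)] = np.empty(0, dtype=int)
            continue
        sub = mem1[rows]
        for j in range(cover.b):
            bins[(i, j)] = rows[sub[:, j]]
    return bins


def select_epsilon(data: np.ndarray, k: int = 3) -> float:
    """Smallest epsilon such that every point has >= k neighbors within it.

    Equals the maximum over points of the Euclidean distance to the k-th
    nearest neighbor.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if k < 1:
        raise ParameterError("k must be >= 1")
    if data.shape[0] < k + 1:
        raise ParameterError(f"need at least {k + 1} points for k={k}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(data)
    dist, _ = nn.kneighbors(data)
    return float(dist[:, k].max())


def cluster_bin(
    bin_points: np.ndarray, epsilon: float, min_neighbors: int = 3
) -> list[np.ndarray]:
    """Density-based clusters of one bin's preimage.

    Core point: has >= ``min_neighbors`` *other* points within ``epsilon``.
    Clusters are connected components of core points, with border points
    attached to their nearest core; remaining noise points are returned as
    singleton clusters (no point is ever dropped).  Returned as arrays of
    local indices, ordered by smallest member.
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    pts = np.asarray(bin_points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    m = pts.shape[0]
    if m == 0:
        return []
    if m == 1:
        return [np.array([0])]

    dist = squareform(pdist(pts))
    within = dist <= epsilon
    n_other = within.sum(axis=1) - 1
    core = n_other >= min_neighbors

    clusters: list[np.ndarray] = []
    assigned = np.full(m, -1, dtype=int)
    if core.any():
        core_idx = np.flatnonzero(core)
        adj = csr_matrix(within[np.ix_(core_idx, core_idx)])
        n_comp, comp = csgraph.connected_components(adj, directed=False)
        assigned[core_idx] = comp
        # Border points: attach to the component of the nearest core point.
        non_core = np.flatnonzero(~core)
        if non_core.size:
            d_to_core = dist[np.ix_(non_core, core_idx)]
            nearest = np.argmin(d_to_core, axis=1)
            reachable = d_to_core[np.arange(non_core.size), nearest] <= epsilon
            assigned[non_core[reachable]] = comp[nearest[reachable]]
        for c in range(n_comp):
            clusters.append(np.flatnonzero(assigned == c))
    for i in np.flatnonzero(assigned == -1):
        clusters.append(np.array([i]))
    clusters.sort(key=lambda a: int(a[0]))
    return clusters


@dataclass
class ShapeGraph:
    """Mapper output graph.

    Nodes are integers ``0..n_nodes-1``; node attributes: ``members`` (tuple
    of frame indices), ``size`` and ``label_counts`` (dict label -> count,
    only when labels were provided).
    """

    graph: nx.Graph
    n_frames: int
    labels: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def node_order(self) -> list[int]:
        return sorted(self.graph.nodes)

    def members(self, v: int) -> tuple[int, ...]:
        return self.graph.nodes[v]["members"]

    def label_counts(self, v: int) -> dict[str, int]:
        return self.graph.nodes[v].get("label_counts", {})

    def label_nodes(self, label: str) -> list[int]:
        """Nodes containing at least one frame of ``label``."""
        return [v for v in self.node_order if self.label_counts(v).get(label, 0) > 0]

    def present_labels(self) -> set[str]:
        out: set[str] = set()
        for v in self.graph.nodes:
            out.update(k for k, c in self.label_counts(v).items() if c > 0)
        return out

    def n_components(self) -> int:
        return nx.number_connected_components(self.graph) if self.n_nodes else 0

    def largest_component(self) -> tuple["ShapeGraph", float]:
        """Restrict to the largest connected component.

        Returns the restricted graph (nodes relabeled ``0..m-1`` in original
        order) and the fraction of distinct frames whose every node was
        discarded.
        """
        if self.n_nodes == 0 or nx.is_connected(self.graph):
            return self, 0.0
        comps = sorted(nx.connected_components(self.graph),
                       key=lambda c: (-sum(self.graph.nodes[v]["size"] for v in c),
                                      min(c)))
        keep = sorted(comps[0])
        sub = self.graph.subgraph(keep).copy()
        mapping = {v: i for i, v in enumerate(keep)}
        sub = nx.relabel_nodes(sub, mapping)
        kept_frames: set[int] = set()
        for v in sub.nodes:
            kept_frames.update(sub.nodes[v]["members"])
        all_frames: set[int] = set()
        for v in self.graph.nodes:
            all_frames.update(self.graph.nodes[v]["members"])
        discarded = 1.0 - len(kept_frames) / len(all_frames)
        return ShapeGraph(graph=sub, n_frames=self.n_frames, labels=self.labels), discarded


def build_graph(
    clusters: list[np.ndarray],
    labels: np.ndarray | None = None,
    n_frames: int | None = None,
) -> ShapeGraph:
    """Assemble the shape graph from per-bin clusters of global frame indices.

    One node per cluster; an edge joins two nodes iff their member sets
    intersect.  Per-node label counts are tallied from ``labels``.
    """
    members = [np.asarray(c, dtype=int) for c in clusters]
    covered: set[int] = set()
    for c in members:
        covered.update(int(i) for i in c)
    if n_frames is None:
        n_frames = (max(covered) + 1) if covered else 0
    elif covered != set(range(n_frames)):
        # full-coverage contract only when the caller states the frame count
        raise ValidationError("clusters must collectively cover all frames")
    if labels is not None and len(labels) != n_frames:
        raise ValidationError("labels length must equal the number of frames")

    order = sorted(range(len(members)), key=lambda i: (tuple(sorted(members[i])),))
    g = nx.Graph()
    frame_to_nodes: dict[int, list[int]] = {}
    for node, ci in enumerate(order):
        mem = tuple(int(i) for i in sorted(members[ci]))
        attrs: dict = {"members": mem, "size": len(mem)}
        if labels is not None:
            counts: dict[str, int] = {}
            for f in mem:
                lab = str(labels[f])
                counts[lab] = counts.get(lab, 0) + 1
            attrs["label_counts"] = counts
        g.add_node(node, **attrs)
        for f in mem:
            frame_to_nodes.setdefault(f, []).append(node)
    for nodes in frame_to_nodes.values():
        for a in range(len(nodes)):
            for b_ in range(a + 1, len(nodes)):
                g.add_edge(nodes[a], nodes[b_])
    return ShapeGraph(graph=g, n_frames=n_frames,
                      labels=None if labels is None else np.asarray(labels, dtype=object))


def expected_points_per_nonempty_bin(n: int, b: int, p: float, f_empty: float) -> float:
    """Closed-form average number of points per nonempty cover bin.

    ``n / ((b + p - b*p)**2 * (1 - f_empty))`` — the count per effective bin
    divided by the nonempty-bin fraction.
    """
    if b < 1:
        raise ParameterError("b must be >= 1")
    if not 0.0 <= p < 1.0:
        raise ParameterError("p must lie in [0, 1)")
    if not 0.0 <= f_empty < 1.0:
        raise ParameterError("f_empty must lie in [0, 1)")
    if n < 0:
        raise ParameterError("n must be >= 0")
    effective_bins = (b + p - b * p) ** 2
    return n / (effective_bins * (1.0 - f_empty))


def mapper_graph(
    data: np.ndarray,
    labels: np.ndarray | None = None,
    *,
    filter_method: str = "linear",
    seed: int = 0,
    bins: int = 30,
    overlap: float = 0.5,
    k: int = 3,
    min_neighbors: int = 3,
    epsilon: float | None = None,
) -> ShapeGraph:
    """Run the full Mapper construction on one labeled point cloud."""
    data = np.asarray(data, dtype=float)
    embedding = fit_filter(data, method=filter_method, seed=seed)
    cover = build_cover(embedding, b=bins, p=overlap)
    bin_map = assign_bins(embedding, cover)
    if epsilon is None:
        epsilon = select_epsilon(data, k=k)
    clusters: list[np.ndarray] = []
    for key in sorted(bin_map):
        idx = bin_map[key]
        if idx.size == 0:
            continue
        for local in cluster_bin(data[idx], epsilon, min_neighbors=min_neighbors):
            clusters.append(idx[local])
    return build_graph(clusters, labels=labels, n_frames=data.shape[0])
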