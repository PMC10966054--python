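"""Topological descriptors of labeled shape graphs.

For each state label ``l`` the graph carries a probability distribution
``mu_l`` over nodes (normalized within-node label proportions).  Descriptors:

* exact 1-Wasserstein optimal-transport distance between two label
  distributions with the geodesic hop-count matrix as ground cost,
* label-weighted closeness and degree centrality,
* label diameter (longest geodesic between any two ``l`` nodes).

Optimal transport is solved exactly as a linear program (HiGHS).  Two
equivalent formulations are provided: the coupling LP (returns the optimal
transport plan) and a min-cost-flow LP on the graph's edges (much faster on
large graphs, cost only).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.sparse import csgraph

from .exceptions import (
    DegenerateDataError,
    DisconnectedSupportError,
    EmptyLabelError,
    ParameterError,
)
from .mapper import ShapeGraph
from .synthetic import STATES

__all__ = [
    "TransportPlan",
    "label_distribution",
    "geodesic_matrix",
    "ot_distance",
    "ot_cost",
    "closeness_vector",
    "closeness_centrality",
    "degree_centrality",
    "label_diameter",
    "WITHIN_SESSION_PAIRS",
    "CROSS_SESSION_PAIRS",
    "MEASURE_COLUMNS",
    "compute_all_measures",
]

_NORM_TOL = 1e-9


@dataclass
class TransportPlan:
    """An optimal coupling between two node distributions."""

    coupling: np.ndarray
    cost: float


def label_distribution(
    graph: ShapeGraph, label: str, mode: str = "proportion"
) -> np.ndarray:
    """Probability vector ``mu_l`` over nodes for one state label.

    ``proportion`` (default): per node, the within-node fraction of label-l
    frames, renormalized over nodes.  ``count``: per node raw label-l frame
    counts, renormalized (sensitivity-analysis alternative).
    """
    if mode not in ("proportion", "count"):
        raise ParameterError(f"unknown mode {mode!r}")
    order = graph.node_order
    raw = np.empty(len(order))
    for i, v in enumerate(order):
        counts = graph.label_counts(v)
        c = counts.get(label, 0)
        if mode == "proportion":
            size = graph.graph.nodes[v]["size"]
            raw[i] = c / size if size else 0.0
        else:
            raw[i] = c
    total = raw.sum()
    if total <= 0:
        raise EmptyLabelError(f"label {label!r} absent from graph")
    return raw / total


def geodesic_matrix(graph: ShapeGraph) -> np.ndarray:
    """All-pairs shortest-path hop counts; ``inf`` marks unreachable pairs."""
    if graph.n_nodes == 0:
        raise ParameterError("graph must have at least one node")
    adj = nx.to_scipy_sparse_array(graph.graph, nodelist=graph.node_order,
                                   format="csr")
    return csgraph.shortest_path(adj, method="D", unweighted=True, directed=False)


def _check_marginals(D: np.ndarray, p: np.ndarray, q: np.ndarray) -> None:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or p.shape != (n,) or q.shape != (n,):
        raise ParameterError("D, p, q must have matching sizes")
    for name, vec in (("p", p), ("q", q)):
        if np.any(vec < -_NORM_TOL):
            raise ParameterError(f"{name} must be non-negative")
        if abs(vec.sum() - 1.0) > 1e-6:
            raise ParameterError(f"{name} must sum to 1")


def _support_union(D: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    sup = np.flatnonzero((p > 0) | (q > 0))
    if not np.all(np.isfinite(D[np.ix_(sup, sup)])):
        raise DisconnectedSupportError(
            "distribution supports lie in different graph components"
        )
    return sup


def ot_distance(
    D: np.ndarray, p: np.ndarray, q: np.ndarray
) -> tuple[float, TransportPlan]:
    """Exact 1-Wasserstein distance and an optimal transport plan.

    Solves ``min sum_ij D_ij mu_ij`` over couplings with marginals ``p`` and
    ``q`` as a linear program on the support union.
    """
    D = np.asarray(D, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    _check_marginals(D, p, q)
    _support_union(D, p, q)

    sp = np.flatnonzero(p > 0)
    sq = np.flatnonzero(q > 0)
    ns, nt = len(sp), len(sq)
    cost_vec = D[np.ix_(sp, sq)].ravel()

    rows, cols, vals = [], [], []
    for i in range(ns):  # row marginals
        for j in range(nt):
            rows.append(i)
            cols.append(i * nt + j)
            vals.append(1.0)
    for j in range(nt):  # column marginals
        for i in range(ns):
            rows.append(ns + j)
            cols.append(i * nt + j)
            vals.append(1.0)
    a_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(ns + nt, ns * nt))
    b_eq = np.concatenate([p[sp], q[sq]])
    res = linprog(cost_vec, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - guarded by the support check
        raise DisconnectedSupportError(f"transport LP failed: {res.message}")
    coupling = np.zeros_like(D)
    coupling[np.ix_(sp, sq)] = res.x.reshape(ns, nt)
    cost = float(res.fun)
    return cost, TransportPlan(coupling=coupling, cost=cost)


def ot_cost(D: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Exact 1-Wasserstein cost via the min-cost-flow (Beckmann) LP.

    Valid because the ground cost is the geodesic metric of the unit-weight
    graph whose edges are exactly the pairs at hop distance 1.  Far fewer LP
    variables than the coupling formulation; no plan is produced.
    """
    D = np.asarray(D, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    _check_marginals(D, p, q)
    _support_union(D, p, q)
    if np.allclose(p, q, atol=1e-15):
        return 0.0

    iu, ju = np.nonzero(np.triu(D == 1.0, k=1))
    n = D.shape[0]
    n_arcs = 2 * len(iu)
    if n_arcs == 0:
        raise DisconnectedSupportError("no edges available for transport")
    tail = np.concatenate([iu, ju])
    head = np.concatenate([ju, iu])
    rows = np.concatenate([tail, head])
    cols = np.concatenate([np.arange(n_arcs), np.arange(n_arcs)])
    vals = np.concatenate([np.ones(n_arcs), -np.ones(n_arcs)])
    a_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n_arcs))
    res = linprog(np.ones(n_arcs), A_eq=a_eq, b_eq=p - q, bounds=(0, None),
                  method="highs")
    if not res.success:  # pragma: no cover
        raise DisconnectedSupportError(f"flow LP failed: {res.message}")
    return float(res.fun)


def closeness_vector(graph: ShapeGraph, D: np.ndarray | None = None) -> np.ndarray:
    """Per-node closeness: reachable count over summed geodesics; isolated -> 0."""
    if D is None:
        D = geodesic_matrix(graph)
    n = D.shape[0]
    cc = np.zeros(n)
    for v in range(n):
        finite = np.isfinite(D[v])
        finite[v] = False
        r = int(finite.sum())
        if r > 0:
            cc[v] = r / D[v, finite].sum()
    return cc


def closeness_centrality(
    graph: ShapeGraph, mu: np.ndarray, D: np.ndarray | None = None
) -> float:
    """``mu``-weighted arithmetic mean of per-node closeness centrality."""
    mu = np.asarray(mu, dtype=float)
    return float(mu @ closeness_vector(graph, D))


def degree_centrality(graph: ShapeGraph, mu: np.ndarray) -> float:
    """``mu``-weighted mean of degree / (N - 1)."""
    n = graph.n_nodes
    if n < 2:
        raise DegenerateDataError("degree centrality undefined for < 2 nodes")
    mu = np.asarray(mu, dtype=float)
    deg = np.array([graph.graph.degree[v] for v in graph.node_order], dtype=float)
    return float(mu @ (deg / (n - 1)))


def label_diameter(
    graph: ShapeGraph, label: str, D: np.ndarray | None = None
) -> float:
    """Longest geodesic between any two nodes containing ``label``.

    Paths may traverse non-label nodes.  A single label node gives 0; label
    nodes in different components raise :class:`DisconnectedSupportError`.
    """
    nodes = graph.label_nodes(label)
    if not nodes:
        raise EmptyLabelError(f"label {label!r} absent from graph")
    if len(nodes) == 1:
        return 0.0
    if D is None:
        D = geodesic_matrix(graph)
    sub = D[np.ix_(nodes, nodes)]
    if not np.all(np.isfinite(sub)):
        raise DisconnectedSupportError(
            f"label {label!r} nodes lie in different components"
        )
    return float(sub.max())


WITHIN_SESSION_PAIRS: tuple[tuple[str, str], ...] = (
    ("FA1", "OM1"), ("FA1", "RS1"), ("OM1", "RS1"),
    ("FA2", "OM2"), ("FA2", "RS2"), ("OM2", "RS2"),
)
CROSS_SESSION_PAIRS: tuple[tuple[str, str], ...] = (
    ("FA1", "FA2"), ("OM1", "OM2"), ("RS1", "RS2"),
)

MEASURE_COLUMNS: tuple[str, ...] = tuple(
    [f"{m}_{s}" for m in ("dc", "cc", "diam") for s in STATES]
    + [f"d_{a}_{b}" for a, b in WITHIN_SESSION_PAIRS + CROSS_SESSION_PAIRS]
)


def compute_all_measures(
    graph: ShapeGraph,
    subject_id: str | None = None,
    group: str | None = None,
    *,
    mode: str = "proportion",
    distance_pairs: tuple[tuple[str, str], ...] | None = None,
) -> dict:
    """One tidy measure-table row for a subject's shape graph.

    Fields that cannot be computed (absent label, disconnected support,
    degenerate graph) are reported as ``NaN``; the row is still emitted.
    ``distance_pairs`` restricts the OT distances computed (default: all
    within-session and cross-session pairs).
    """
    if distance_pairs is None:
        distance_pairs = WITHIN_SESSION_PAIRS + CROSS_SESSION_PAIRS
    row: dict = {}
    if subject_id is not None:
        row["subject_id"] = subject_id
    if group is not None:
        row["group"] = group

    D = geodesic_matrix(graph)
    cc_vec = closeness_vector(graph, D)
    dists: dict[str, np.ndarray] = {}
    for s in STATES:
        try:
            dists[s] = label_distribution(graph, s, mode=mode)
        except EmptyLabelError:
            pass

    for s in STATES:
        mu = dists.get(s)
        if mu is None:
            row[f"dc_{s}"] = np.nan
            row[f"cc_{s}"] = np.nan
            row[f"diam_{s}"] = np.nan
            continue
        try:
            row[f"dc_{s}"] = degree_centrality(graph, mu)
        except DegenerateDataError:
            row[f"dc_{s}"] = np.nan
        row[f"cc_{s}"] = float(mu @ cc_vec)
        try:
            row[f"diam_{s}"] = label_diameter(graph, s, D)
        except DisconnectedSupportError:
            row[f"diam_{s}"] = np.nan

    for a, b in distance_pairs:
        key = f"d_{a}_{b}"
        pa, qb = dists.get(a), dists.get(b)
        if pa is None or qb is None:
            row[key] = np.nan
            continue
        try:
            row[key] = ot_cost(D, pa, qb)
        except DisconnectedSupportError:
            row[key] = np.nan
    return row
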