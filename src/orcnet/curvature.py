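"""Ollivier-Ricci curvature over per-sample weighted graphs.

For an edge (i, j) of a weighted sample graph, the curvature is

    kappa(i, j) = 1 - W1(mu_i, mu_j) / d(i, j)

where mu_i is the neighbor measure of i (mass r_k / sum r over N(i) on
each neighbor k), W1 is the Wasserstein-1 (earth mover's) distance under
the graph's shortest-path metric, and d(i, j) is the weighted
shortest-path distance between the endpoints with edge lengths
1/sqrt(w). Positive curvature marks redundantly connected, "hub-like"
edges; negative curvature marks bottleneck "bridge-like" edges whose
removal would disconnect local traffic.

Transport problems are solved exactly as small linear programs (HiGHS);
no entropic regularization is used, so results are deterministic and
reproducible to solver precision. Before each solve, mass shared by the
two measures at the same support node is cancelled — valid because the
ground cost is a metric, so optimal plans never move shared mass — which
substantially shrinks the LPs on overlapping neighborhoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.sparse.csgraph import dijkstra

from .config import GraphConfig
from .net_io import CohortTables
from .sample_graph import WeightedSampleGraph, build_weighted_graph, node_values

logger = logging.getLogger(__name__)

MASS_TOL = 1e-9


@dataclass(frozen=True)
class CurvatureRecord:
    """Curvature of a single edge: endpoints, W1, distance and kappa."""

    edge: tuple[str, str]
    w1: float
    d: float
    kappa: float


def _length_matrix(g: WeightedSampleGraph, ground_metric: str = "weighted") -> sparse.csr_matrix:
    n = g.n_nodes
    i, j = g.edges[:, 0], g.edges[:, 1]
    vals = g.lengths if ground_metric == "weighted" else np.ones(len(i))
    m = sparse.coo_matrix((vals, (i, j)), shape=(n, n))
    return (m + m.T).tocsr()


def shortest_path_distance(g: WeightedSampleGraph, i: int, j: int,
                           ground_metric: str = "weighted") -> float:
    """Weighted shortest-path distance d(i, j) = min over paths of sum of lengths.

    For adjacent nodes this may be smaller than the direct edge length
    when a multi-edge bypass is shorter.
    """
    if i == j:
        raise ValueError("distance requested between identical nodes")
    lengths = _length_matrix(g, ground_metric)
    dist = dijkstra(lengths, directed=False, indices=[i])[0]
    if not np.isfinite(dist[j]):
        raise ValueError(f"nodes {g.nodes[i]!r} and {g.nodes[j]!r} are disconnected")
    return float(dist[j])


def _transport_cost(a: np.ndarray, b: np.ndarray, cost: np.ndarray) -> float:
    """Exact optimal-transport cost between nonnegative equal-mass vectors.

    Solves min <C, X> s.t. X 1 = a, X^T 1 = b, X >= 0 with HiGHS. The
    last column constraint is dropped (redundant given equal masses).
    """
    m, n = cost.shape
    if m == 0:
        return 0.0
    if m == 1:
        return float(b @ cost[0])
    if n == 1:
        return float(a @ cost[:, 0])
    data, rows, cols = [], [], []
    for k in range(m):
        rows.extend([k] * n)
        cols.extend(range(k * n, (k + 1) * n))
        data.extend([1.0] * n)
    for l in range(n - 1):
        rows.extend([m + l] * m)
        cols.extend(range(l, m * n, n))
        data.extend([1.0] * m)
    A_eq = sparse.csr_matrix((data, (rows, cols)), shape=(m + n - 1, m * n))
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def _reduce_common_mass(
    sup_a: np.ndarray, p: np.ndarray, sup_b: np.ndarray, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cancel mass shared at identical support nodes (metric ground cost)."""
    p = p.copy()
    q = q.copy()
    common, ia, ib = np.intersect1d(sup_a, sup_b, return_indices=True)
    if len(common):
        shared = np.minimum(p[ia], q[ib])
        p[ia] -= shared
        q[ib] -= shared
    keep_a = p > MASS_TOL
    keep_b = q > MASS_TOL
    return sup_a[keep_a], p[keep_a], sup_b[keep_b], q[keep_b]


def wasserstein1(mu_i: np.ndarray, mu_j: np.ndarray, ground: np.ndarray) -> float:
    """W1 between two probability vectors on a common support.

    ``ground`` is the matrix of pairwise distances between the support
    points (the shortest-path metric restricted to the support). Raises
    if either vector's mass deviates from 1 beyond 1e-9.
    """
    mu_i = np.asarray(mu_i, dtype=float)
    mu_j = np.asarray(mu_j, dtype=float)
    if abs(mu_i.sum() - 1.0) > MASS_TOL or abs(mu_j.sum() - 1.0) > MASS_TOL:
        raise ValueError("probability vectors must each sum to 1 within 1e-9")
    idx = np.arange(len(mu_i))
    sa, p, sb, q = _reduce_common_mass(idx, mu_i, idx, mu_j)
    if len(sa) == 0 or len(sb) == 0:
        return 0.0
    return _transport_cost(p, q, np.asarray(ground, dtype=float)[np.ix_(sa, sb)])


def _edge_w1(g: WeightedSampleGraph, i: int, j: int, dist: np.ndarray) -> float:
    """W1(mu_i, mu_j) given the full-graph distance matrix ``dist``."""
    na, nb = g.neighbors[i], g.neighbors[j]
    p = g.r[na] / g.r[na].sum()
    q = g.r[nb] / g.r[nb].sum()
    sa, p, sb, q = _reduce_common_mass(na, p, nb, q)
    if len(sa) == 0 or len(sb) == 0:
        return 0.0
    return _transport_cost(p, q, dist[np.ix_(sa, sb)])


def _solve_lp_batch(batch: list[tuple[np.ndarray, np.ndarray, np.ndarray]]) -> list[float]:
    """Solve several independent transport LPs as one block-diagonal LP.

    Blocks do not interact, so the combined optimum decomposes into the
    per-block optima; batching only amortizes solver call overhead.
    """
    c_parts, rows, cols, data, b_parts = [], [], [], [], []
    row0 = col0 = 0
    spans = []
    for a, b, cost in batch:
        m, n = cost.shape
        c_parts.append(cost.ravel())
        rows.extend(np.repeat(np.arange(row0, row0 + m), n))
        cols.extend(range(col0, col0 + m * n))
        data.extend([1.0] * (m * n))
        for l in range(n - 1):
            rows.extend([row0 + m + l] * m)
            cols.extend(range(col0 + l, col0 + m * n, n))
            data.extend([1.0] * m)
        b_parts.append(a)
        b_parts.append(b[:-1])
        spans.append((col0, col0 + m * n))
        row0 += m + n - 1
        col0 += m * n
    c = np.concatenate(c_parts)
    b_eq = np.concatenate(b_parts)
    A_eq = sparse.csr_matrix((data, (rows, cols)), shape=(row0, col0))
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"batched transport LP failed: {res.message}")
    x = res.x
    return [float(c[s:e] @ x[s:e]) for s, e in spans]


_LP_BATCH = 32


def _all_edge_w1(g: WeightedSampleGraph, dist: np.ndarray) -> np.ndarray:
    """W1(mu_i, mu_j) for every edge, with batched LP solves."""
    w1 = np.zeros(g.n_edges)
    batch: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    batch_idx: list[int] = []
    for e, (i, j) in enumerate(g.edges):
        na, nb = g.neighbors[i], g.neighbors[j]
        p = g.r[na] / g.r[na].sum()
        q = g.r[nb] / g.r[nb].sum()
        sa, p, sb, q = _reduce_common_mass(na, p, nb, q)
        if len(sa) == 0 or len(sb) == 0:
            w1[e] = 0.0
        elif len(sa) == 1:
            w1[e] = float(q @ dist[sa[0], sb])
        elif len(sb) == 1:
            w1[e] = float(p @ dist[sa, sb[0]])
        else:
            batch.append((p, q, dist[np.ix_(sa, sb)]))
            batch_idx.append(e)
    for k in range(0, len(batch), _LP_BATCH):
        vals = _solve_lp_batch(batch[k:k + _LP_BATCH])
        for off, v in enumerate(vals):
            w1[batch_idx[k + off]] = v
    return w1


def orc_edge(g: WeightedSampleGraph, i: int, j: int,
             config: GraphConfig | None = None) -> CurvatureRecord:
    """Curvature record for a single edge (i, j), given by node index."""
    config = config or GraphConfig()
    edge_set = {tuple(e) for e in g.edges.tolist()}
    if (i, j) not in edge_set and (j, i) not in edge_set:
        raise ValueError(f"({g.nodes[i]}, {g.nodes[j]}) is not an edge")
    lengths = _length_matrix(g, config.ground_metric)
    sources = np.unique(np.concatenate([g.neighbors[i], g.neighbors[j], [i]]))
    dist_rows = dijkstra(lengths, directed=False, indices=sources)
    dist = np.full((g.n_nodes, g.n_nodes), np.inf)
    dist[sources] = dist_rows
    d = dist[i, j] if np.isfinite(dist[i, j]) else None
    if d is None or d <= 0:
        raise ValueError("invalid endpoint distance")
    w1 = _edge_w1(g, i, j, dist)
    return CurvatureRecord(edge=(g.nodes[i], g.nodes[j]), w1=w1, d=float(d),
                           kappa=1.0 - w1 / float(d))


def curvature_for_sample(g: WeightedSampleGraph,
                         config: GraphConfig | None = None) -> np.ndarray:
    """Kappa for every edge of one sample's weighted graph (edge order fixed)."""
    config = config or GraphConfig()
    lengths = _length_matrix(g, config.ground_metric)
    dist = dijkstra(lengths, directed=False)
    if not np.isfinite(dist).all():
        raise ValueError("sample graph is disconnected")
    w1 = _all_edge_w1(g, dist)
    d = dist[g.edges[:, 0], g.edges[:, 1]]
    return 1.0 - w1 / d


def edge_labels(g: WeightedSampleGraph) -> list[str]:
    """Stable 'geneA|geneB' labels in the pipeline's fixed edge order."""
    return [f"{g.nodes[i]}|{g.nodes[j]}" for i, j in g.edges]


def curvature_matrix(cohort: CohortTables, kind: str = "rna",
                     config: GraphConfig | None = None) -> pd.DataFrame:
    """Edges x samples curvature matrix for a harmonized cohort.

    ``kind`` selects the node-value source: ``rna`` uses the TPM matrix
    (log2(TPM+1) transform), ``cna`` the copy-number matrix. Columns are
    samples in cohort order; rows are 'geneA|geneB' edge labels in the
    fixed lexicographic edge order.
    """
    config = config or GraphConfig()
    if kind == "rna":
        matrix = cohort.matrices["tpm"]
    elif kind == "cna":
        matrix = cohort.matrices["cna"]
    else:
        raise ValueError(f"unknown curvature source kind {kind!r}")
    nodes = cohort.genes
    columns = {}
    labels = None
    for s_idx, sample in enumerate(cohort.samples):
        try:
            r = node_values(matrix, sample, config)
        except Exception as exc:
            raise RuntimeError(f"node values failed for sample {sample!r}: {exc}") from exc
        g = build_weighted_graph(cohort.network, r, nodes=nodes)
        if labels is None:
            labels = edge_labels(g)
        columns[sample] = curvature_for_sample(g, config)
        if (s_idx + 1) % 25 == 0:
            logger.info("curvature: %d/%d samples done", s_idx + 1, len(cohort.samples))
    return pd.DataFrame(columns, index=pd.Index(labels, name="edge"))


def write_curvature_matrix(curv: pd.DataFrame, path) -> None:
    curv.to_csv(path, sep="\t")


def read_curvature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="edge")
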