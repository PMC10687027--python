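"""Brute-force reference implementations for curvature testing.

Deliberately naive and independent of the production code paths:
shortest paths are found by exhaustive simple-path enumeration, and the
transport problem is solved by enumerating every vertex of the
transportation polytope (all basis subsets of the constraint matrix;
bases of transportation problems are totally unimodular, so singular
candidates are detected exactly). Only usable on tiny graphs — that is
the point.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def oracle_shortest_path(net: nx.Graph, lengths: dict[tuple[str, str], float],
                         source, target) -> float:
    """Minimum total length over all simple paths, by full enumeration."""

    def edge_len(a, b):
        return lengths[(a, b)] if (a, b) in lengths else lengths[(b, a)]

    if source == target:
        return 0.0
    best = np.inf
    for path in nx.all_simple_paths(net, source, target):
        total = sum(edge_len(a, b) for a, b in zip(path[:-1], path[1:]))
        best = min(best, total)
    if not np.isfinite(best):
        raise ValueError(f"no path between {source!r} and {target!r}")
    return float(best)


def oracle_transport(a: np.ndarray, b: np.ndarray, cost: np.ndarray) -> float:
    """Optimal transport cost by exhaustive vertex enumeration.

    Every vertex of {X >= 0, X 1 = a, X^T 1 = b} is a basic solution
    supported on m + n - 1 cells; all such cell subsets are enumerated,
    the square system solved in batch, and the cheapest feasible vertex
    returned. Complexity explodes combinatorially: supports larger than
    ~4x4 are refused.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cost = np.asarray(cost, dtype=float)
    m, n = cost.shape
    if abs(a.sum() - b.sum()) > 1e-9:
        raise ValueError("marginal masses differ")
    if m == 1:
        return float(b @ cost[0])
    if n == 1:
        return float(a @ cost[:, 0])
    r = m + n - 1
    cells = m * n
    if cells > 20:
        raise ValueError(f"support {m}x{n} too large for exhaustive enumeration")

    # Constraint matrix with the last column constraint dropped (redundant).
    A = np.zeros((r, cells))
    for k in range(m):
        A[k, k * n:(k + 1) * n] = 1.0
    for l in range(n - 1):
        A[m + l, l::n] = 1.0
    rhs = np.concatenate([a, b[:-1]])

    combos = np.array(list(combinations(range(cells), r)))
    bases = A[:, combos].transpose(1, 0, 2)          # (ncomb, r, r)
    dets = np.abs(np.linalg.det(bases))
    valid = dets > 0.5                                # TU matrix: |det| is 0 or 1
    if not valid.any():
        raise RuntimeError("no nonsingular basis found")
    x = np.linalg.solve(bases[valid], np.broadcast_to(rhs, (int(valid.sum()), r))[..., None])[..., 0]
    feasible = (x >= -1e-9).all(axis=1)
    if not feasible.any():
        raise RuntimeError("no feasible vertex found")
    costs = np.einsum("ij,ij->i", x[feasible], cost.ravel()[combos[valid][feasible]])
    return float(costs.min())


def oracle_orc_edge(net: nx.Graph, r: dict[str, float], i, j) -> float:
    """Curvature of edge (i, j) built entirely from the brute-force parts.

    Recomputes transition probabilities, edge weights and lengths
    directly from the defining formulas, takes ground distances from the
    simple-path oracle, and solves the transport problem by vertex
    enumeration. No common-mass cancellation is applied.
    """
    if not net.has_edge(i, j):
        raise ValueError(f"({i!r}, {j!r}) is not an edge")

    def mu(node):
        nbrs = sorted(net.neighbors(node))
        total = sum(r[k] for k in nbrs)
        return nbrs, np.array([r[k] / total for k in nbrs])

    lengths = {}
    for a, b in net.edges():
        p_ab = r[b] / sum(r[k] for k in net.neighbors(a))
        p_ba = r[a] / sum(r[k] for k in net.neighbors(b))
        w = 0.5 * (p_ab + p_ba)
        lengths[(a, b)] = 1.0 / np.sqrt(w)

    sup_i, mu_i = mu(i)
    sup_j, mu_j = mu(j)
    ground = np.array([[oracle_shortest_path(net, lengths, x, y) if x != y else 0.0
                        for y in sup_j] for x in sup_i])
    w1 = oracle_transport(mu_i, mu_j, ground)
    d = oracle_shortest_path(net, lengths, i, j)
    return 1.0 - w1 / d


def random_small_graph(rng: np.random.Generator, n_max: int = 8,
                       max_degree: int = 4) -> nx.Graph:
    """Random connected graph with n <= n_max nodes and bounded degree.

    Built as a uniform random spanning tree plus a few extra edges that
    respect the degree cap, keeping every transport support small enough
    for the vertex-enumeration oracle.
    """
    n = int(rng.integers(3, n_max + 1))
    g = nx.Graph()
    labels = [f"g{k}" for k in range(n)]
    g.add_node(labels[0])
    for k in range(1, n):
        attach = labels[int(rng.integers(0, k))]
        while g.degree[attach] >= max_degree:
            attach = labels[int(rng.integers(0, k))]
        g.add_edge(labels[k], attach)
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        a, b = rng.choice(n, size=2, replace=False)
        a, b = labels[a], labels[b]
        if a != b and not g.has_edge(a, b) and g.degree[a] < max_degree and g.degree[b] < max_degree:
            g.add_edge(a, b)
    return g
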