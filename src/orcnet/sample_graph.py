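"""Per-sample weighted graph construction.

Each patient sample turns the fixed interactome into a weighted graph:
omics values become node values r_k, node values become random-walk
transition probabilities p_ij = r_j / sum_{k in N(i)} r_k for adjacent
i,j, edge weights are the symmetrized w_ij = (p_ij + p_ji)/2, and edge
lengths are 1/sqrt(w_ij). The curvature stage consumes this graph.

Because transition probabilities are ratios of node values, multiplying
all node values by a positive constant leaves the weighted graph
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import GraphConfig


@dataclass
class WeightedSampleGraph:
    """One sample's weighted interactome in array form.

    Nodes are indexed 0..n-1 in the order of ``nodes``; ``neighbors[i]``
    is the integer array of i's neighbors; ``r`` the node values;
    ``edges`` the (m, 2) array of index pairs with i < j ordered
    lexicographically; ``weights``/``lengths`` the per-edge w_ij and
    1/sqrt(w_ij).
    """

    nodes: list[str]
    neighbors: list[np.ndarray]
    r: np.ndarray
    edges: np.ndarray
    weights: np.ndarray
    lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, gene: str) -> int:
        return self.nodes.index(gene)

    def neighbor_sum(self, i: int) -> float:
        return float(self.r[self.neighbors[i]].sum())

    def transition_probability(self, i: int, j: int) -> float:
        """p_ij = r_j / sum of r over N(i); zero if (i, j) is not an edge."""
        if j not in self.neighbors[i]:
            return 0.0
        return float(self.r[j] / self.neighbor_sum(i))


def node_values(matrix, sample: str, config: GraphConfig | None = None) -> np.ndarray:
    """Per-gene node values r for one sample.

    RNA (``tpm``): r = log2(TPM + 1) + eps. Copy number (``cna``): with
    ``copy_number`` encoding, r = max(value, 0) + eps; with ``log_ratio``
    encoding values are first mapped to copy-number scale as 2^value * 2.
    The floor eps keeps every node value strictly positive so transition
    probabilities and edge lengths are always defined.
    """
    if config is None:
        config = GraphConfig()
    if sample not in matrix.values.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    x = matrix.values[sample].to_numpy(dtype=float)
    eps = config.pseudocount_eps
    if matrix.kind == "tpm":
        if (x < 0).any():
            raise ValueError("negative TPM values")
        r = np.log2(x + 1.0) + eps
    elif matrix.kind == "cna":
        if config.cna_encoding == "log_ratio":
            x = np.exp2(x) * 2.0
        elif config.cna_encoding != "copy_number":
            raise ValueError(f"unknown cna_encoding {config.cna_encoding!r}")
        r = np.maximum(x, 0.0) + eps
    else:
        raise ValueError(f"cannot derive node values from kind {matrix.kind!r}")
    if eps > 0 and not (r > 0).all():
        raise AssertionError("node values not strictly positive")
    return r


def neighbor_distribution(g: WeightedSampleGraph, i: int) -> tuple[np.ndarray, np.ndarray]:
    """The measure mu_i: support (neighbor indices) and probabilities.

    mu_i places mass r_k / sum_{k' in N(i)} r_k' on each neighbor k of i
    and no mass on i itself.
    """
    nbrs = g.neighbors[i]
    if len(nbrs) == 0:
        raise ValueError(f"node {g.nodes[i]!r} is isolated")
    probs = g.r[nbrs] / g.r[nbrs].sum()
    return nbrs, probs


def build_weighted_graph(net: nx.Graph, r: dict[str, float] | np.ndarray,
                         nodes: list[str] | None = None) -> WeightedSampleGraph:
    """Assemble the weighted graph for one sample.

    ``r`` maps every node to a strictly positive value, either as a dict
    keyed by gene or as an array aligned with ``nodes`` (sorted node
    order by default). Edge order is lexicographic by
    (min endpoint, max endpoint) and fixed across the whole pipeline.
    """
    if nodes is None:
        nodes = sorted(net.nodes())
    idx = {gene: k for k, gene in enumerate(nodes)}
    if isinstance(r, dict):
        r_arr = np.array([r[gene] for gene in nodes], dtype=float)
    else:
        r_arr = np.asarray(r, dtype=float)
        if len(r_arr) != len(nodes):
            raise ValueError("r does not cover all nodes")
    if not (r_arr > 0).all():
        raise ValueError("node values must be strictly positive")

    neighbors = [np.array(sorted(idx[v] for v in net.neighbors(gene)), dtype=np.int64)
                 for gene in nodes]
    denom = np.array([r_arr[nb].sum() for nb in neighbors])

    edge_pairs = sorted(
        ((i, j) if nodes[i] < nodes[j] else (j, i) for i, j in
         ((idx[a], idx[b]) for a, b in net.edges())),
        key=lambda e: (nodes[e[0]], nodes[e[1]]),
    )
    edges = np.array(edge_pairs, dtype=np.int64).reshape(-1, 2)

    i_arr, j_arr = edges[:, 0], edges[:, 1]
    p_ij = r_arr[j_arr] / denom[i_arr]
    p_ji = r_arr[i_arr] / denom[j_arr]
    weights = 0.5 * (p_ij + p_ji)
    assert (weights > 0).all()
    lengths = 1.0 / np.sqrt(weights)
    return WeightedSampleGraph(nodes=list(nodes), neighbors=neighbors, r=r_arr,
                               edges=edges, weights=weights, lengths=lengths)
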