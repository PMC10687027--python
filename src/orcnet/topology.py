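"""Network topology: degree classes, k-hop neighborhoods, edge robustness.

Genes are classified by interactome degree — singleton (exactly one
connection), hub (more than twice the network's mean degree), bridge
(everything in between). Local context is extracted as 1-hop/2-hop
induced subgraphs (hop distance, not weighted distance). Per-edge
robustness is the difference of median curvature between the high- and
low-risk groups: a positive delta means the interaction is more robust
in the high-risk group, a negative delta more fragile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import RiskGrouping


@dataclass
class DegreeClassification:
    """Degree-based gene classes with the thresholds that produced them."""

    classes: pd.Series        # gene -> singleton | bridge | hub
    mean_degree: float
    hub_threshold: float      # hub iff degree > threshold (strict)

    def genes_in(self, cls: str) -> list[str]:
        return list(self.classes[self.classes == cls].index)


def classify_degrees(net: nx.Graph) -> DegreeClassification:
    """Classify every gene as singleton, bridge or hub.

    Hub threshold is twice the mean degree, applied strictly: with mean
    degree 8.4 a gene is a hub iff it forms more than 16 connections.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = dict(net.degree())
    mean_degree = 2 * net.number_of_edges() / net.number_of_nodes()
    threshold = 2 * mean_degree

    def cls(d: int) -> str:
        if d == 1:
            return "singleton"
        if d > threshold:
            return "hub"
        return "bridge"

    classes = pd.Series({g: cls(d) for g, d in degrees.items()}, name="degree_class")
    return DegreeClassification(classes=classes.sort_index(), mean_degree=mean_degree,
                                hub_threshold=threshold)


def khop_subgraph(net: nx.Graph, gene: str, k: int) -> nx.Graph:
    """Induced subgraph on nodes within hop distance k of ``gene`` (k in {1, 2})."""
    if gene not in net:
        raise KeyError(f"gene {gene!r} not in network")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    return nx.ego_graph(net, gene, radius=k)


def edge_robustness_delta(curv: pd.DataFrame, risk: RiskGrouping | pd.Series) -> pd.DataFrame:
    """Median-curvature difference per edge between risk groups.

    Returns a frame indexed by edge label with median_high, median_low,
    delta = high - low, and label: robust (delta > 0), fragile
    (delta < 0), unchanged (delta == 0).
    """
    assignment = risk.assignment if isinstance(risk, RiskGrouping) else risk
    high = [s for s in curv.columns if assignment.get(s) == "high"]
    low = [s for s in curv.columns if assignment.get(s) == "low"]
    if not high or not low:
        raise ValueError("both risk groups must contain at least one sample")
    med_high = curv[high].median(axis=1)
    med_low = curv[low].median(axis=1)
    delta = med_high - med_low
    label = pd.Series(np.select([delta > 0, delta < 0], ["robust", "fragile"],
                                default="unchanged"), index=curv.index)
    return pd.DataFrame({"median_high": med_high, "median_low": med_low,
                         "delta": delta, "label": label})


def _edge_label(a: str, b: str) -> str:
    return f"{min(a, b)}|{max(a, b)}"


def neighborhood_report(net: nx.Graph, curv: pd.DataFrame,
                        risk: RiskGrouping | pd.Series, gene: str, k: int) -> dict:
    """Node-link JSON description of a gene's k-hop neighborhood.

    Nodes carry their degree class (computed on the full network); links
    carry the robustness delta and label from ``edge_robustness_delta``.
    Edges without curvature data (absent from ``curv``) get delta None
    and label 'unknown'.
    """
    sub = khop_subgraph(net, gene, k)
    classes = classify_degrees(net).classes
    deltas = edge_robustness_delta(curv, risk)
    nodes = [{"id": n, "degree_class": classes[n]} for n in sorted(sub.nodes())]
    links = []
    for a, b in sorted(tuple(sorted(e)) for e in sub.edges()):
        lab = _edge_label(a, b)
        if lab in deltas.index:
            row = deltas.loc[lab]
            links.append({"source": a, "target": b,
                          "delta": float(row["delta"]), "label": row["label"]})
        else:
            links.append({"source": a, "target": b, "delta": None, "label": "unknown"})
    return {"focal_gene": gene, "k": k, "nodes": nodes, "links": links}


def write_neighborhood_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


def read_neighborhood_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
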