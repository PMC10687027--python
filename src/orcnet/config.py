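"""Configuration dataclasses shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GraphConfig:
    """Node-value transformation for per-sample graph weighting.

    pseudocount_eps: strictly positive floor added to transformed node
        values so transition probabilities and edge lengths stay defined
        even at zero expression.
    rna_transform: only ``log2p1`` (r = log2(TPM+1) + eps) is supported.
    cna_encoding: ``copy_number`` (values are absolute copies, floored at
        0) or ``log_ratio`` (values are log2 ratios, mapped to copies as
        2^value * 2 before flooring).
    ground_metric: metric used as the transport ground distance —
        ``weighted`` (the graph's shortest-path metric under edge lengths
        1/sqrt(w), also used in the curvature denominator) or ``hop``
        (unweighted shortest path), exposed for sensitivity analysis.
    """

    pseudocount_eps: float = 0.01
    rna_transform: str = "log2p1"
    cna_encoding: str = "copy_number"
    ground_metric: str = "weighted"

    def __post_init__(self) -> None:
        if self.pseudocount_eps < 0:
            raise ValueError("pseudocount_eps must be >= 0")
        if self.rna_transform != "log2p1":
            raise ValueError(f"unknown rna_transform {self.rna_transform!r}")
        if self.cna_encoding not in ("copy_number", "log_ratio"):
            raise ValueError(f"unknown cna_encoding {self.cna_encoding!r}")
        if self.ground_metric not in ("weighted", "hop"):
            raise ValueError(f"unknown ground_metric {self.ground_metric!r}")


@dataclass(frozen=True)
class ClusterConfig:
    """Hierarchical clustering of the per-sample curvature features.

    Ward linkage on Euclidean distance by default; the number of
    clusters is chosen by mean silhouette over k_min..k_max (ties to the
    smallest k). Per-feature standardization is off by default.
    """

    linkage: str = "ward"
    metric: str = "euclidean"
    k_min: int = 2
    k_max: int = 12
    standardize: bool = False
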