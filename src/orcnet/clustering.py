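"""Patient subtyping from curvature features.

Samples are clustered by hierarchical agglomerative clustering (Ward
linkage on Euclidean distance by default) on the transposed curvature
matrix, with the number of clusters chosen by mean silhouette score.
Clusters are then merged into high/low-risk groups either manually
(fidelity to published groupings) or automatically by ranking clusters
on median Kaplan-Meier survival. Genomic annotation (hyperdiploidy) and
cluster-feature association (Fisher's exact test) live here too.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .config import ClusterConfig

logger = logging.getLogger(__name__)

HYPERDIPLOID_CHROMOSOMES = frozenset({"3", "5", "7", "9", "11", "15", "19", "21"})


def feature_matrix(curv: pd.DataFrame, standardize: bool = False) -> pd.DataFrame:
    """Samples x edges feature matrix (transposed curvature matrix).

    With ``standardize`` each edge column is centred and scaled to unit
    variance; constant edges carry no information and are dropped with a
    warning.
    """
    if curv.empty:
        raise ValueError("empty curvature matrix")
    X = curv.T.copy()
    if standardize:
        sd = X.std(axis=0, ddof=0)
        constant = sd[sd == 0].index
        if len(constant):
            logger.warning("dropping %d constant edge feature(s)", len(constant))
            X = X.drop(columns=constant)
            sd = sd.drop(constant)
        X = (X - X.mean(axis=0)) / sd
    return X


def hierarchical_cluster(X: pd.DataFrame, k: int,
                         config: ClusterConfig | None = None) -> pd.Series:
    """Agglomerative clustering into k groups; labels 1..k.

    Labels are renumbered by first appearance in sample order so the
    assignment is deterministic given X and the configuration.
    """
    config = config or ClusterConfig()
    n = len(X)
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} samples")
    model = AgglomerativeClustering(n_clusters=k, linkage=config.linkage,
                                    metric=config.metric)
    raw = model.fit_predict(X.to_numpy())
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for idx, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[idx] = relabel[lab]
    return pd.Series(labels, index=X.index, name="cluster")


def select_k_silhouette(X: pd.DataFrame, k_range=None,
                        config: ClusterConfig | None = None) -> tuple[int, dict[int, float]]:
    """Choose k maximizing mean silhouette; ties go to the smallest k.

    Singleton clusters contribute silhouette 0 (scikit-learn's
    convention), avoiding the divide-by-zero a one-member cluster would
    otherwise cause.
    """
    config = config or ClusterConfig()
    n = len(X)
    if k_range is None:
        k_range = range(config.k_min, min(config.k_max, n - 1) + 1)
    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ValueError("empty k range")
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValueError("k range must lie within [2, n_samples - 1]")
    scores: dict[int, float] = {}
    arr = X.to_numpy()
    for k in k_range:
        labels = hierarchical_cluster(X, k, config)
        scores[k] = float(silhouette_score(arr, labels.to_numpy(), metric="euclidean"))
    best = max(sorted(scores), key=lambda k: (scores[k], -k))
    return best, scores


@dataclass
class RiskGrouping:
    """High/low risk assignment per sample with its provenance."""

    assignment: pd.Series  # sample -> {high, low, excluded}
    provenance: str        # manual | auto
    cluster_of: pd.Series  # source cluster labels

    @property
    def high(self) -> list[str]:
        return list(self.assignment[self.assignment == "high"].index)

    @property
    def low(self) -> list[str]:
        return list(self.assignment[self.assignment == "low"].index)


def assign_risk_groups(
    assign: pd.Series,
    clinical: pd.DataFrame,
    mode: str = "auto",
    mapping: dict[int, str] | None = None,
    quantile: float = 1 / 3,
) -> RiskGrouping:
    """Merge clusters into high/low-risk groups.

    manual: ``mapping`` sends cluster labels to 'high'/'low'/'excluded'
    verbatim (unnamed clusters are excluded). auto: clusters are ranked
    by median Kaplan-Meier survival time and accumulated from the worst
    end into the high-risk group and from the best end into the low-risk
    group until each tail holds at least ``quantile`` of the samples
    (whole clusters only, at least one per tail); the middle is
    excluded. Accumulating sample mass rather than counting clusters
    keeps tiny clusters from becoming degenerate one-patient groups.
    """
    clusters = sorted(assign.unique())
    if len(clusters) < 2:
        raise ValueError("risk grouping needs at least two clusters")
    if mode == "manual":
        if mapping is None:
            raise ValueError("manual mode requires a mapping")
        unknown = set(mapping) - set(clusters)
        if unknown:
            raise ValueError(f"mapping names unknown cluster(s): {sorted(unknown)}")
        bad = set(mapping.values()) - {"high", "low", "excluded"}
        if bad:
            raise ValueError(f"mapping values must be high/low/excluded, got {sorted(bad)}")
        out = assign.map(lambda c: mapping.get(c, "excluded"))
        return RiskGrouping(assignment=out.rename("risk"), provenance="manual",
                            cluster_of=assign)
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")

    from .survival import km_estimate  # local import to avoid a cycle

    med: dict[int, float] = {}
    for c in clusters:
        samples = assign[assign == c].index
        sub = clinical.loc[clinical["sample"].isin(samples)]
        curve = km_estimate(sub["pfs_time"].to_numpy(), sub["event"].to_numpy())
        med[c] = curve.median_survival_time
    order = sorted(clusters, key=lambda c: (med[c], c))
    sizes = assign.value_counts()
    target = quantile * len(assign)

    def take(ranked: list[int], blocked: set[int]) -> set[int]:
        # grow the tail while whole clusters bring it closer to the
        # target sample mass (always at least one cluster)
        chosen: set[int] = set()
        cum = 0
        for c in ranked:
            if c in blocked:
                break
            size = int(sizes[c])
            if chosen and abs(cum + size - target) > abs(cum - target):
                break
            chosen.add(c)
            cum += size
        return chosen

    high_clusters = take(order, set())
    low_clusters = take(list(reversed(order)), high_clusters)
    if not low_clusters:
        raise ValueError("risk quantile leaves no low-risk cluster")

    def tag(c: int) -> str:
        if c in high_clusters:
            return "high"
        if c in low_clusters:
            return "low"
        return "excluded"

    out = assign.map(tag)
    return RiskGrouping(assignment=out.rename("risk"), provenance="auto",
                        cluster_of=assign)


def _normalize_chrom(name: str) -> str:
    s = str(name)
    return s[3:] if s.lower().startswith("chr") else s


KNOWN_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])


def annotate_hyperdiploidy(segments: pd.DataFrame, gain_copy: float = 2.0,
                           min_fraction: float = 0.60, min_chromosomes: int = 3) -> pd.Series:
    """Flag hyperdiploid samples from a per-sample copy-number segment table.

    A sample is hyperdiploid when more than two (i.e. >= 3) of
    chromosomes 3, 5, 7, 9, 11, 15, 19, 21 have gains (copy state above
    ``gain_copy``) covering more than 60% of the chromosome's segmented
    length. Columns required: sample, chrom, start, end, copy_state.
    """
    required = {"sample", "chrom", "start", "end", "copy_state"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns {sorted(missing)}")
    seg = segments.copy()
    seg["chrom"] = seg["chrom"].map(_normalize_chrom)
    unknown = set(seg["chrom"]) - KNOWN_CHROMOSOMES
    if unknown:
        logger.warning("ignoring unknown chromosome name(s): %s", sorted(unknown))
        seg = seg[seg["chrom"].isin(KNOWN_CHROMOSOMES)]
    seg["length"] = seg["end"] - seg["start"]
    if (seg["length"] <= 0).any():
        raise ValueError("segments must have end > start")

    flags: dict[str, bool] = {}
    for sample, sub in seg.groupby("sample"):
        n_gained = 0
        for chrom, csub in sub.groupby("chrom"):
            if chrom not in HYPERDIPLOID_CHROMOSOMES:
                continue
            total = csub["length"].sum()
            gained = csub.loc[csub["copy_state"] > gain_copy, "length"].sum()
            if total > 0 and gained / total > min_fraction:
                n_gained += 1
        flags[sample] = n_gained >= min_chromosomes
    return pd.Series(flags, name="hyperdiploid")


def cluster_feature_association(assign: pd.Series, feature: pd.Series,
                                cluster: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test of a boolean feature vs one cluster.

    Returns (odds ratio, p). The 2x2 table is (in-cluster vs rest) x
    (feature vs not); a degenerate table (a constant margin) returns
    p = 1 with odds ratio NaN.
    """
    common = assign.index.intersection(feature.index)
    a = assign.loc[common]
    f = feature.loc[common].astype(bool)
    in_c = a == cluster
    if in_c.sum() == 0:
        raise ValueError(f"cluster {cluster} is empty")
    if (~in_c).sum() == 0:
        raise ValueError("no samples outside the cluster")
    table = np.array([
        [int((in_c & f).sum()), int((in_c & ~f).sum())],
        [int((~in_c & f).sum()), int((~in_c & ~f).sum())],
    ])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return float("nan"), 1.0
    oddsratio, p = stats.fisher_exact(table, alternative="two-sided")
    return float(oddsratio), float(p)
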