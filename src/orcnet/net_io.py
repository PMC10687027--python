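"""Input/output and cohort harmonization.

Reads the standard inputs of the analysis — a protein-interaction edge
list over gene symbols, gene-by-sample omics matrices (TPM, read counts,
copy number), a per-sample clinical table, and GMT gene-set collections —
and restricts everything to the largest connected component of the genes
shared by all sources.

Gene symbols are treated as case-sensitive opaque strings; no alias or
identifier mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OMICS_KINDS = ("tpm", "counts", "cna")


@dataclass(frozen=True)
class OmicsMatrix:
    """Gene-by-sample numeric matrix with a declared modality.

    ``values`` is a genes x samples DataFrame; ``kind`` is one of
    ``tpm`` (non-negative), ``counts`` (non-negative integers) or
    ``cna`` (real, encoding declared elsewhere).
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in OMICS_KINDS:
            raise ValueError(f"unknown omics kind {self.kind!r}; expected one of {OMICS_KINDS}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene labels in omics matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample labels in omics matrix")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("omics matrix contains non-finite values")
        if self.kind in ("tpm", "counts") and (vals < 0).any():
            raise ValueError(f"{self.kind} matrix contains negative entries")
        if self.kind == "counts" and not np.allclose(vals, np.round(vals)):
            raise ValueError("counts matrix contains non-integer entries")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CohortTables:
    """Harmonized view of a cohort: aligned matrices + clinical table.

    All matrices share the same gene order (rows) and sample order
    (columns); ``network`` is the largest connected component of the
    interactome restricted to those genes.
    """

    network: nx.Graph
    matrices: dict[str, OmicsMatrix]
    clinical: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        first = next(iter(self.matrices.values()))
        return first.genes

    @property
    def samples(self) -> list[str]:
        first = next(iter(self.matrices.values()))
        return first.samples


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column tab-separated gene-symbol edge list.

    Duplicate pairs (in either order) are collapsed and self-loops are
    dropped with a logged count. Raises on an empty file or a line with
    fewer than two fields.
    """
    path = Path(path)
    g = nx.Graph()
    n_self = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            a, b = fields[0], fields[1]
            n_lines += 1
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_self:
        logger.warning("dropped %d self-loop(s) from %s", n_self, path)
    return g


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write edges as a 2-column TSV, each edge once with sorted endpoints."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{a}\t{b}\n")


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken deterministically by picking the
    component containing the lexicographically smallest gene symbol.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(net))
    max_size = max(len(c) for c in comps)
    candidates = [c for c in comps if len(c) == max_size]
    best = min(candidates, key=min)
    return net.subgraph(best).copy()


def read_omics_matrix(path: str | Path, kind: str) -> OmicsMatrix:
    """Read a TSV with genes as rows (first column ``gene``), samples as columns."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be named 'gene', got {df.columns[0]!r}")
    df = df.set_index("gene")
    return OmicsMatrix(values=df, kind=kind)


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.rename_axis("gene").to_csv(path, sep="\t")


CLINICAL_REQUIRED = ("sample", "pfs_time", "event")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical TSV: sample, pfs_time, event, [iss], [covariates...]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return validate_clinical(df)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    if df["sample"].duplicated().any():
        raise ValueError("clinical table has duplicated sample IDs")
    t = df["pfs_time"].to_numpy(dtype=float)
    if not np.isfinite(t).all() or (t <= 0).any():
        raise ValueError("pfs_time must be finite and positive")
    ev = set(df["event"].unique())
    if not ev <= {0, 1}:
        raise ValueError(f"event must be 0/1, got {sorted(ev)}")
    return df.set_index("sample", drop=False)


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene...

    The description field is ignored; duplicate set names raise.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = genes
    return sets


def harmonize(
    net: nx.Graph,
    matrices: Mapping[str, OmicsMatrix],
    clinical: pd.DataFrame,
) -> CohortTables:
    """Restrict network + matrices + clinical table to shared genes/samples.

    Genes are intersected across the network and every matrix, the
    largest connected component is re-extracted, and samples are
    restricted to those present in every matrix and the clinical table.
    Row/column orders are made identical across matrices (genes sorted,
    samples in clinical-table order).
    """
    clinical = validate_clinical(clinical.reset_index(drop=True))
    genes = set(net.nodes())
    for m in matrices.values():
        genes &= set(m.genes)
    if not genes:
        raise ValueError("no genes shared between the network and all matrices")
    sub = net.subgraph(genes)
    if sub.number_of_edges() == 0:
        raise ValueError("shared genes induce an edgeless network")
    lcc = largest_connected_component(sub)
    kept_genes = sorted(lcc.nodes())

    samples: list[str] = [s for s in clinical["sample"] if all(s in m.values.columns for m in matrices.values())]
    if not samples:
        raise ValueError("no samples shared between the clinical table and all matrices")

    out = {
        key: OmicsMatrix(values=m.values.loc[kept_genes, samples], kind=m.kind)
        for key, m in matrices.items()
    }
    clin = clinical[clinical["sample"].isin(samples)].copy()
    clin = clin.set_index("sample", drop=False).loc[samples]
    logger.info(
        "harmonized cohort: %d genes (LCC), %d edges, %d samples",
        len(kept_genes), lcc.number_of_edges(), len(samples),
    )
    return CohortTables(network=lcc, matrices=dict(out), clinical=clin)
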