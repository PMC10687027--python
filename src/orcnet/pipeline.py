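"""End-to-end pipeline: one config file in, a run manifest out.

Stages run in dependency order — cohort (simulate or ingest), curvature,
cluster, risk, survival, diffexp (+ optional enrichment), topology —
each writing its outputs under the run directory. A stage whose output
files already exist is skipped, so deleting one stage's outputs and
re-running recomputes only that stage and nothing upstream. The manifest
records the config hash, a checksum for every file read or written,
stage timings, the package version and the seed; deterministic stages
reproduce identical checksums on identical inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, net_io
from .clustering import (assign_risk_groups, feature_matrix,
                         hierarchical_cluster, select_k_silhouette)
from .config import ClusterConfig, GraphConfig
from .curvature import curvature_matrix, read_curvature_matrix, write_curvature_matrix
from .diffexp import hypergeom_enrichment, nb_two_group_test, select_significant
from .simulate import SimulationConfig, simulate, write_cohort
from .survival import cox_univariate, km_by_group, logrank_by_label, logrank_pairwise
from .topology import classify_degrees, edge_robustness_delta, neighborhood_report, \
    write_neighborhood_report

logger = logging.getLogger(__name__)

STAGES = ("cohort", "curvature", "cluster", "risk", "survival", "diffexp", "topology")

_SCHEMA: dict[str, type | tuple] = {
    "seed": int,
    "out_dir": str,
    "simulate": dict,
    "inputs": dict,
    "graph": dict,
    "curvature": dict,
    "cluster": dict,
    "risk": dict,
    "diffexp": dict,
    "topology": dict,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    """Schema check before any computation; returns the config with defaults."""
    unknown = set(config) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key, typ in _SCHEMA.items():
        if key in config and not isinstance(config[key], typ):
            raise ValueError(f"config key {key!r} must be {typ}")
    if "out_dir" not in config:
        raise ValueError("config must set out_dir")
    if ("simulate" in config) == ("inputs" in config):
        raise ValueError("config must set exactly one of 'simulate' or 'inputs'")
    if "inputs" in config:
        required = {"network", "tpm", "counts", "cna", "clinical"}
        missing = required - set(config["inputs"])
        if missing:
            raise ValueError(f"inputs missing {sorted(missing)}")
    config.setdefault("seed", 0)
    for key in ("graph", "curvature", "cluster", "risk", "diffexp", "topology"):
        config.setdefault(key, {})
    config["curvature"].setdefault("kind", "rna")
    config["cluster"].setdefault("k", "auto")
    config["risk"].setdefault("mode", "auto")
    config["diffexp"].setdefault("q_max", 0.05)
    config["diffexp"].setdefault("lfc_min", 3.5)
    config["topology"].setdefault("k", 2)
    return config


class PipelineRun:
    """Executes the stages of one configured run with simple file caching."""

    def __init__(self, config: dict):
        self.config = validate_config(dict(config))
        self.out = Path(self.config["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True, default=str).encode()).hexdigest(),
            "seed": self.config["seed"],
            "version": __version__,
            "stages": {},
            "files": {},
        }

    # -- helpers -----------------------------------------------------------

    def _paths(self, stage: str) -> dict[str, Path]:
        o = self.out
        if stage == "cohort":
            keys = ("network", "counts", "tpm", "cna", "segments", "clinical")
            p = {k: o / "cohort" / f"{k}.tsv" for k in keys}
            if "simulate" in self.config:
                p["ground_truth"] = o / "cohort" / "ground_truth.json"
            return p
        if stage == "curvature":
            return {"curvature": o / "curvature.tsv"}
        if stage == "cluster":
            return {"labels": o / "cluster" / "labels.tsv",
                    "silhouette": o / "cluster" / "silhouette.json"}
        if stage == "risk":
            return {"risk": o / "cluster" / "risk.tsv"}
        if stage == "survival":
            return {"logrank": o / "survival" / "logrank.json",
                    "pairwise": o / "survival" / "logrank_pairwise.tsv",
                    "km": o / "survival" / "km_curves.tsv",
                    "cox": o / "survival" / "cox_univariate.tsv"}
        if stage == "diffexp":
            p = {"de": o / "de" / "de_results.tsv",
                 "significant": o / "de" / "significant.tsv"}
            if self.config["diffexp"].get("gmt"):
                p["enrichment"] = o / "de" / "enrichment.tsv"
            return p
        if stage == "topology":
            return {"degree_classes": o / "topology" / "degree_classes.tsv",
                    "edge_deltas": o / "topology" / "edge_deltas.tsv"}
        raise KeyError(stage)

    def _cached(self, stage: str) -> bool:
        return all(p.exists() for p in self._paths(stage).values())

    def _record(self, stage: str, elapsed: float, skipped: bool) -> None:
        paths = self._paths(stage)
        self.manifest["stages"][stage] = {
            "seconds": round(elapsed, 3),
            "skipped": skipped,
            "outputs": [str(p) for p in paths.values()],
        }
        for p in paths.values():
            self.manifest["files"][str(p)] = _sha256(p)

    # -- stages ------------------------------------------------------------

    def _load_cohort(self) -> net_io.CohortTables:
        p = self._paths("cohort")
        net = net_io.read_edge_list(p["network"])
        matrices = {
            "tpm": net_io.read_omics_matrix(p["tpm"], "tpm"),
            "counts": net_io.read_omics_matrix(p["counts"], "counts"),
            "cna": net_io.read_omics_matrix(p["cna"], "cna"),
        }
        clinical = net_io.read_clinical_table(p["clinical"])
        return net_io.harmonize(net, matrices, clinical)

    def _stage_cohort(self) -> None:
        p = self._paths("cohort")
        (self.out / "cohort").mkdir(exist_ok=True)
        if "simulate" in self.config:
            sim_cfg = dict(self.config["simulate"])
            sim_cfg.setdefault("seed", self.config["seed"])
            cohort = simulate(SimulationConfig(**sim_cfg))
            write_cohort(cohort, self.out / "cohort")
        else:
            inputs = self.config["inputs"]
            for key, src in inputs.items():
                self.manifest["files"][str(src)] = _sha256(Path(src))
            net = net_io.read_edge_list(inputs["network"])
            net_io.write_edge_list(net, p["network"])
            for key in ("tpm", "counts", "cna"):
                m = net_io.read_omics_matrix(inputs[key], key if key != "tpm" else "tpm")
                net_io.write_omics_matrix(m, p[key])
            clin = net_io.read_clinical_table(inputs["clinical"])
            net_io.write_clinical_table(clin, p["clinical"])
            if inputs.get("segments"):
                seg = pd.read_csv(inputs["segments"], sep="\t")
            else:
                seg = pd.DataFrame(columns=["sample", "chrom", "start", "end", "copy_state"])
            seg.to_csv(p["segments"], sep="\t", index=False)

    def _stage_curvature(self, cohort: net_io.CohortTables) -> None:
        graph_cfg = GraphConfig(**self.config["graph"])
        curv = curvature_matrix(cohort, kind=self.config["curvature"]["kind"],
                                config=graph_cfg)
        write_curvature_matrix(curv, self._paths("curvature")["curvature"])

    def _stage_cluster(self, curv: pd.DataFrame) -> None:
        p = self._paths("cluster")
        p["labels"].parent.mkdir(exist_ok=True)
        cc = self.config["cluster"]
        cluster_cfg = ClusterConfig(
            linkage=cc.get("linkage", "ward"),
            k_min=cc.get("k_min", 2), k_max=cc.get("k_max", 12),
            standardize=cc.get("standardize", False))
        X = feature_matrix(curv, standardize=cluster_cfg.standardize)
        if cc["k"] == "auto":
            k, scores = select_k_silhouette(X, config=cluster_cfg)
        else:
            k, scores = int(cc["k"]), {}
        labels = hierarchical_cluster(X, k, cluster_cfg)
        labels.rename_axis("sample").to_frame().to_csv(p["labels"], sep="\t")
        with open(p["silhouette"], "w") as fh:
            json.dump({"k": k, "scores": scores}, fh, indent=1)

    def _stage_risk(self, labels: pd.Series, cohort: net_io.CohortTables) -> None:
        rc = self.config["risk"]
        mapping = None
        if rc["mode"] == "manual":
            mapping = {int(k): v for k, v in rc["mapping"].items()}
        risk = assign_risk_groups(labels, cohort.clinical, mode=rc["mode"],
                                  mapping=mapping,
                                  quantile=rc.get("quantile", 1 / 3))
        risk.assignment.rename_axis("sample").to_frame().to_csv(
            self._paths("risk")["risk"], sep="\t")

    def _stage_survival(self, labels: pd.Series, risk: pd.Series,
                        cohort: net_io.CohortTables) -> None:
        p = self._paths("survival")
        p["logrank"].parent.mkdir(exist_ok=True)
        stat, df, pval = logrank_by_label(cohort.clinical, labels)
        logrank_pairwise(cohort.clinical, labels).to_csv(
            p["pairwise"], sep="\t", index=False)
        hl = risk[risk.isin(["high", "low"])]
        stat_hl, _, p_hl = logrank_by_label(cohort.clinical, hl)
        with open(p["logrank"], "w") as fh:
            json.dump({"clusters": {"statistic": stat, "df": df, "p": pval},
                       "risk_groups": {"statistic": stat_hl, "p": p_hl}}, fh, indent=1)
        rows = []
        for lab, curve in km_by_group(cohort.clinical, labels).items():
            for t, s in zip(curve.times, curve.survival):
                rows.append((lab, t, s))
        pd.DataFrame(rows, columns=["group", "time", "survival"]).to_csv(
            p["km"], sep="\t", index=False)
        cox = cox_univariate(cohort.matrices["tpm"].values, cohort.clinical)
        cox.table.to_csv(p["cox"], sep="\t", index=False)

    def _stage_diffexp(self, risk: pd.Series, cohort: net_io.CohortTables) -> None:
        p = self._paths("diffexp")
        p["de"].parent.mkdir(exist_ok=True)
        dc = self.config["diffexp"]
        de = nb_two_group_test(cohort.matrices["counts"].values, risk)
        de.to_csv(p["de"], sep="\t", index=False)
        sig = select_significant(de, q_max=dc["q_max"], lfc_min=dc["lfc_min"])
        sig.to_csv(p["significant"], sep="\t", index=False)
        if dc.get("gmt"):
            sets = net_io.read_gmt(dc["gmt"])
            enr = hypergeom_enrichment(list(sig["gene"]), sets, cohort.genes)
            enr.to_csv(p["enrichment"], sep="\t", index=False)

    def _stage_topology(self, curv: pd.DataFrame, risk: pd.Series,
                        cohort: net_io.CohortTables) -> None:
        p = self._paths("topology")
        p["degree_classes"].parent.mkdir(exist_ok=True)
        classes = classify_degrees(cohort.network)
        classes.classes.rename_axis("gene").to_frame().to_csv(
            p["degree_classes"], sep="\t")
        deltas = edge_robustness_delta(curv, risk)
        deltas.rename_axis("edge").to_csv(p["edge_deltas"], sep="\t")
        tc = self.config["topology"]
        for gene in tc.get("genes", []):
            report = neighborhood_report(cohort.network, curv, risk, gene, tc["k"])
            write_neighborhood_report(
                report, p["degree_classes"].parent / f"neighborhood_{gene}.json")

    # -- driver ------------------------------------------------------------

    def run(self) -> dict:
        cohort = None
        curv = None
        labels = None
        risk = None
        try:
            for stage in STAGES:
                t0 = time.time()
                skipped = self._cached(stage)
                if not skipped:
                    if stage == "cohort":
                        self._stage_cohort()
                    elif stage == "curvature":
                        cohort = cohort or self._load_cohort()
                        self._stage_curvature(cohort)
                    elif stage == "cluster":
                        curv = curv if curv is not None else read_curvature_matrix(
                            self._paths("curvature")["curvature"])
                        self._stage_cluster(curv)
                    elif stage == "risk":
                        cohort = cohort or self._load_cohort()
                        labels = labels if labels is not None else pd.read_csv(
                            self._paths("cluster")["labels"], sep="\t",
                            index_col="sample")["cluster"]
                        self._stage_risk(labels, cohort)
                    elif stage in ("survival", "diffexp", "topology"):
                        cohort = cohort or self._load_cohort()
                        labels = labels if labels is not None else pd.read_csv(
                            self._paths("cluster")["labels"], sep="\t",
                            index_col="sample")["cluster"]
                        risk = risk if risk is not None else pd.read_csv(
                            self._paths("risk")["risk"], sep="\t",
                            index_col="sample")["risk"]
                        if stage == "survival":
                            self._stage_survival(labels, risk, cohort)
                        elif stage == "diffexp":
                            self._stage_diffexp(risk, cohort)
                        else:
                            curv = curv if curv is not None else read_curvature_matrix(
                                self._paths("curvature")["curvature"])
                            self._stage_topology(curv, risk, cohort)
                    logger.info("stage %s done in %.1fs", stage, time.time() - t0)
                else:
                    logger.info("stage %s skipped (cached)", stage)
                self._record(stage, time.time() - t0, skipped)
        finally:
            with open(self.out / "manifest.json", "w") as fh:
                json.dump(self.manifest, fh, indent=1)
        return self.manifest


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full pipeline from a config dict or YAML file path."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    return PipelineRun(config).run()
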