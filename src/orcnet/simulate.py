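"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the analysis assumes: a scale-free
interactome (Barabasi-Albert, m = 4 giving mean degree near 8, like a
curated protein-interaction network), negative-binomial read counts with
planted subtype expression modules, gene-dosage coupling between copy
number and expression, arm-level copy-number events including a
hyperdiploid subtype, and subtype- and gene-linked exponential survival
with uniform censoring.

Two planted expression layers serve different recovery questions:
per-subtype modules (moderate log2 shift, default 2.0 on 10% of genes
per subtype) carry broad clustering signal, and per-subtype marker sets
(default 25 genes per subtype at log2 shift 4.0) mimic the dramatic
hallmark overexpression that defines real myeloma subtypes (CCND1 under
t(11;14), MMSET under t(4;14), MAF-family translocations). The markers
of the highest- and lowest-hazard subtypes are the planted
differential-expression truth for the high- vs low-risk comparison: up-
and down-regulated respectively, at a magnitude the downstream fold-
change filter is expected to recover.

What it does not emulate: isoform/length structure (gene lengths are
fixed at 1 so TPM coincides with CPM), batch effects, library
preparation artifacts, or mutational processes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import net_io
from .net_io import OmicsMatrix

HYPERDIPLOID_CHROMS = ("3", "5", "7", "9", "11", "15", "19", "21")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort. Defaults define the standard study conditions."""

    n_genes: int = 300
    n_samples: int = 200
    interactome_model: str = "barabasi_albert"   # or "configuration"
    ba_m: int = 4
    target_mean_degree: float = 8.0              # configuration model only
    n_subtypes: int = 3
    module_fraction: float = 0.10                # planted module size per subtype
    module_shift_log2: float = 2.0               # expression shift inside modules
    n_marker_genes: int = 25                     # strong marker genes per subtype
    marker_shift_log2: float = 4.0               # marker shift within the owning subtype
    nb_dispersion: float = 0.2
    library_size: float = 3e5
    dosage_exponent: float = 1.0                 # expression mean scales as (cn/2)^gamma
    gain_fraction: float = 0.70                  # chromosome fraction covered by gains
    n_hyperdiploid_chroms: int = 5               # gained chromosomes in the HRD subtype
    focal_loss_prob: float = 0.10                # random arm loss per non-HRD sample
    baseline_hazard: float = np.log(2) / 3       # median PFS 3 years at baseline
    subtype_log_hr: tuple[float, ...] = (0.0, float(np.log(1.7)), float(np.log(3)))
    n_prognostic_genes: int = 4
    prognostic_beta: float = 0.40                # log-hazard per SD, i.e. HR ~1.5/SD
    censor_horizon: float = 10.0                 # years
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.module_fraction * self.n_genes < 1:
            raise ValueError("module_fraction x n_genes must be >= 1")
        if len(self.subtype_log_hr) != self.n_subtypes:
            raise ValueError("subtype_log_hr length must equal n_subtypes")
        if self.interactome_model not in ("barabasi_albert", "configuration"):
            raise ValueError(f"unknown interactome model {self.interactome_model!r}")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    subtype: dict[str, int]                      # sample -> subtype (1-based)
    module_genes: dict[int, list[str]]           # subtype -> module gene list
    marker_genes: dict[int, list[str]]           # subtype -> strong marker genes
    de_genes: dict[str, float]                   # gene -> expected log2FC, high vs low risk
    prognostic_genes: dict[str, float]           # gene -> planted log-hazard per SD
    hyperdiploid: dict[str, bool]                # sample -> planted flag
    gene_chromosome: dict[str, str]              # gene -> chromosome name

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["subtype"] = {k: int(v) for k, v in d["subtype"].items()}
        d["module_genes"] = {int(k): v for k, v in d["module_genes"].items()}
        d["marker_genes"] = {int(k): v for k, v in d["marker_genes"].items()}
        return cls(**d)


@dataclass
class SimulatedCohort:
    network: nx.Graph
    counts: OmicsMatrix
    tpm: OmicsMatrix
    cna: OmicsMatrix
    segments: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{k:0{width}d}" for k in range(1, n + 1)]


def simulate_interactome(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> nx.Graph:
    """Scale-free interactome over synthetic gene symbols.

    barabasi_albert: preferential attachment with m = cfg.ba_m, giving
    2m(n-m)/n mean degree (about 8 for m = 4 at large n) and a heavy
    degree tail. configuration: a Zipf-like degree sequence rescaled to
    the target mean degree, simplified (self-loops/multi-edges removed)
    and reduced to its largest connected component.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    names = _gene_names(cfg.n_genes)
    if cfg.interactome_model == "barabasi_albert":
        seed = int(rng.integers(0, 2**31 - 1))
        g = nx.barabasi_albert_graph(cfg.n_genes, cfg.ba_m, seed=seed)
        g = nx.relabel_nodes(g, dict(zip(range(cfg.n_genes), names)))
        return g
    # configuration model
    raw = rng.zipf(2.5, size=cfg.n_genes).astype(float)
    raw = np.minimum(raw, cfg.n_genes // 4)
    degs = np.maximum(np.round(raw * cfg.target_mean_degree / raw.mean()), 1).astype(int)
    if degs.sum() % 2:
        degs[0] += 1
    seed = int(rng.integers(0, 2**31 - 1))
    g = nx.configuration_model(degs, seed=seed)
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    g = nx.relabel_nodes(g, dict(zip(range(cfg.n_genes), names)))
    lcc = max(nx.connected_components(g), key=len)
    return g.subgraph(lcc).copy()


def _gene_chromosome_map(genes: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Contiguous blocks of genes per chromosome, chr1..chr22."""
    chroms = [str(i) for i in range(1, 23)]
    blocks = np.array_split(np.arange(len(genes)), len(chroms))
    mapping = {}
    for chrom, idx in zip(chroms, blocks):
        for k in idx:
            mapping[genes[k]] = chrom
    return mapping


def simulate_cohort(net: nx.Graph, cfg: SimulationConfig,
                    rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Simulate counts, TPM, CNA, segments and clinical outcomes on ``net``.

    See the module docstring for the generative model. Sampling is fully
    determined by cfg.seed (or the supplied generator), so identical
    configurations reproduce identical cohorts.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    genes = sorted(net.nodes())
    n_genes = len(genes)
    n = cfg.n_samples
    samples = [f"S{k:04d}" for k in range(1, n + 1)]
    K = cfg.n_subtypes

    subtype = rng.integers(1, K + 1, size=n)

    # Planted gene sets: disjoint modules and marker sets per subtype,
    # then prognostic genes.
    perm = list(rng.permutation(genes))
    module_size = int(round(cfg.module_fraction * n_genes))
    needed = K * (module_size + cfg.n_marker_genes) + cfg.n_prognostic_genes
    if needed > n_genes:
        raise ValueError(f"planted gene sets need {needed} genes but only {n_genes} exist")
    module_genes: dict[int, list[str]] = {}
    marker_genes: dict[int, list[str]] = {}
    pos = 0
    for k in range(1, K + 1):
        module_genes[k] = sorted(perm[pos:pos + module_size])
        pos += module_size
    for k in range(1, K + 1):
        marker_genes[k] = sorted(perm[pos:pos + cfg.n_marker_genes])
        pos += cfg.n_marker_genes
    log_hr = np.asarray(cfg.subtype_log_hr)
    high_subtype = int(np.argmax(log_hr)) + 1
    low_subtype = int(np.argmin(log_hr)) + 1
    prognostic = sorted(perm[pos:pos + cfg.n_prognostic_genes])

    gene_idx = {g: i for i, g in enumerate(genes)}
    gene_chrom = _gene_chromosome_map(genes, rng)

    # --- copy number -----------------------------------------------------
    # Subtype 1 is the hyperdiploid subtype: gains on the first
    # n_hyperdiploid_chroms chromosomes of the canonical list, covering
    # gain_fraction of each. Other samples get at most focal losses.
    hrd_chroms = list(HYPERDIPLOID_CHROMS[: cfg.n_hyperdiploid_chroms])
    chrom_genes: dict[str, list[str]] = {}
    for g in genes:
        chrom_genes.setdefault(gene_chrom[g], []).append(g)
    chrom_len = {c: 1000 * len(gl) for c, gl in chrom_genes.items()}

    cn = np.full((n_genes, n), 2.0)
    seg_rows = []
    hyperdiploid_flags = {}
    all_chroms = sorted(chrom_genes, key=lambda c: int(c))
    for s_i, s in enumerate(samples):
        is_hrd = subtype[s_i] == 1
        hyperdiploid_flags[s] = bool(is_hrd)
        loss_chrom = None
        if not is_hrd and rng.random() < cfg.focal_loss_prob:
            loss_chrom = str(rng.choice(all_chroms))
        for chrom in all_chroms:
            L = chrom_len[chrom]
            gl = chrom_genes[chrom]
            if is_hrd and chrom in hrd_chroms:
                cut = cfg.gain_fraction * L
                seg_rows.append((s, chrom, 0, int(cut), 3))
                seg_rows.append((s, chrom, int(cut), L, 2))
                for g_i, g in enumerate(gl):
                    midpoint = 1000 * g_i + 500
                    if midpoint < cut:
                        cn[gene_idx[g], s_i] = 3.0
            elif chrom == loss_chrom:
                cut = 0.4 * L
                seg_rows.append((s, chrom, 0, int(cut), 1))
                seg_rows.append((s, chrom, int(cut), L, 2))
                for g_i, g in enumerate(gl):
                    if 1000 * g_i + 500 < cut:
                        cn[gene_idx[g], s_i] = 1.0
            else:
                seg_rows.append((s, chrom, 0, L, 2))
    segments = pd.DataFrame(seg_rows, columns=["sample", "chrom", "start", "end", "copy_state"])

    # --- expression ------------------------------------------------------
    base_log2 = rng.normal(4.0, 1.5, size=n_genes)
    baseline = np.exp2(base_log2)
    baseline /= baseline.sum()

    shift = np.zeros((n_genes, n))
    for k in range(1, K + 1):
        cols = subtype == k
        for g in module_genes[k]:
            shift[gene_idx[g], cols] += cfg.module_shift_log2
        for g in marker_genes[k]:
            shift[gene_idx[g], cols] += cfg.marker_shift_log2

    lib = cfg.library_size * np.exp(rng.normal(0.0, 0.25, size=n))
    # library size is the expected total depth, so relative abundances are
    # renormalized per sample; count-level fold changes survive because
    # median-of-ratios size factors absorb per-sample scalars downstream
    mean = baseline[:, None] * np.exp2(shift) * (cn / 2.0) ** cfg.dosage_exponent
    mean = mean / mean.sum(axis=0, keepdims=True) * lib[None, :]

    disp = cfg.nb_dispersion
    if disp > 0:
        lam = rng.gamma(shape=1.0 / disp, scale=mean * disp)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)

    colsum = counts.sum(axis=0, keepdims=True).astype(float)
    if (colsum == 0).any():
        raise RuntimeError("a sample drew zero total counts; increase library_size")
    tpm = counts / colsum * 1e6

    # --- survival --------------------------------------------------------
    # Gene-level hazard uses within-subtype-centred z-scores of realized
    # log2(TPM+1): TPM is compositional, so the planted expression shifts
    # leak a shared per-subtype offset into every other gene's abundance;
    # centring keeps the gene effects orthogonal to the subtype effects
    # and the configured subtype hazard ratios exact.
    logtpm = np.log2(tpm + 1.0)
    lin = np.array([cfg.subtype_log_hr[subtype[s_i] - 1] for s_i in range(n)])
    beta_map = {}
    for g in prognostic:
        row = logtpm[gene_idx[g]]
        sd = row.std(ddof=0)
        z = (row - row.mean()) / sd if sd > 0 else np.zeros(n)
        for k in range(1, K + 1):
            cols = subtype == k
            z[cols] -= z[cols].mean()
        lin = lin + cfg.prognostic_beta * z
        beta_map[g] = cfg.prognostic_beta
    rate = cfg.baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)
    # staggered administrative follow-up: censoring times spread uniformly
    # over the second half of the study horizon
    t_censor = rng.uniform(0.5 * cfg.censor_horizon, cfg.censor_horizon, size=n)
    pfs_time = np.maximum(np.minimum(t_event, t_censor), 1e-4)
    event = (t_event <= t_censor).astype(int)
    iss = rng.choice(["I", "II", "III"], size=n, p=[0.35, 0.35, 0.30])
    clinical = pd.DataFrame({"sample": samples, "pfs_time": pfs_time,
                             "event": event, "iss": iss}).set_index("sample", drop=False)

    de_expect = {g: cfg.marker_shift_log2 for g in marker_genes[high_subtype]}
    de_expect.update({g: -cfg.marker_shift_log2 for g in marker_genes[low_subtype]})
    truth = GroundTruth(
        subtype={s: int(subtype[i]) for i, s in enumerate(samples)},
        module_genes=module_genes,
        marker_genes=marker_genes,
        de_genes=de_expect,
        prognostic_genes=beta_map,
        hyperdiploid=hyperdiploid_flags,
        gene_chromosome=gene_chrom,
    )
    idx = pd.Index(genes, name="gene")
    return SimulatedCohort(
        network=net,
        counts=OmicsMatrix(pd.DataFrame(counts, index=idx, columns=samples), kind="counts"),
        tpm=OmicsMatrix(pd.DataFrame(tpm, index=idx, columns=samples), kind="tpm"),
        cna=OmicsMatrix(pd.DataFrame(cn, index=idx, columns=samples), kind="cna"),
        segments=segments,
        clinical=clinical,
        truth=truth,
    )


def simulate(cfg: SimulationConfig | None = None) -> SimulatedCohort:
    """Interactome + cohort in one call, fully seeded by cfg.seed."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    net = simulate_interactome(cfg, rng)
    return simulate_cohort(net, cfg, rng)


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, str]:
    """Serialize every cohort table in the pipeline's text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "counts": out / "counts.tsv",
        "tpm": out / "tpm.tsv",
        "cna": out / "cna.tsv",
        "segments": out / "segments.tsv",
        "clinical": out / "clinical.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    net_io.write_edge_list(cohort.network, paths["network"])
    net_io.write_omics_matrix(cohort.counts, paths["counts"])
    net_io.write_omics_matrix(cohort.tpm, paths["tpm"])
    net_io.write_omics_matrix(cohort.cna, paths["cna"])
    cohort.segments.to_csv(paths["segments"], sep="\t", index=False)
    net_io.write_clinical_table(cohort.clinical, paths["clinical"])
    cohort.truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
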