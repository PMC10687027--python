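# orcnet

Ollivier-Ricci curvature analysis of omics-weighted gene interaction
networks, for researchers studying how global network robustness
patterns in tumour transcriptomes and copy-number profiles relate to
patient outcome (the motivating setting is multiple myeloma, but
nothing is disease specific).

Single-gene statistics miss effects that live in the *interactions*
between genes. `orcnet` takes a fixed protein-interaction network and,
for each patient sample, weights it with that sample's expression or
copy-number values, then measures every edge's Ollivier-Ricci curvature
(ORC) — a geometric proxy for how robustly two genes stay connected when
the network is perturbed. Patients become points in edge-curvature
space; everything downstream (subtyping, survival, differential
expression, network topology) works from there.

## The statistic

For node values `r_k > 0` (RNA: `log2(TPM+1) + ε`), each node spreads
mass to its neighbours with probability `p_ij = r_j / Σ_{k∈N(i)} r_k`,
edges get weights `w_ij = (p_ij + p_ji)/2` and lengths `1/√w_ij`, and
every edge is scored with

```
κ(i,j) = 1 − W₁(μ_i, μ_j) / d(i,j)
```

where `μ_i` is node i's neighbour measure, `W₁` the Wasserstein-1
(earth mover's) distance under the graph's shortest-path metric, and
`d(i,j)` the weighted shortest-path distance. `κ > 0`: hub-like,
redundantly connected, robust. `κ < 0`: bridge-like, fragile — a
candidate bottleneck. Transport is solved as an exact LP; a brute-force
oracle (exhaustive simple paths + transportation-polytope vertex
enumeration) pins the implementation to 1e-8 on hundreds of random
graphs. See `docs/methods.md` for the full model, defaults and
limitations.

## Worked example

Real cohorts of this kind are access controlled, so the package ships a
generator that plants subtype structure, strong marker genes,
copy-number events and survival effects, and records the ground truth:

```python
from orcnet import (SimulationConfig, simulate, harmonize, curvature_matrix,
                    feature_matrix, select_k_silhouette, hierarchical_cluster,
                    assign_risk_groups, nb_two_group_test, select_significant)
from orcnet.survival import logrank_by_label

sim = simulate(SimulationConfig(n_genes=150, n_samples=80, seed=7))
cohort = harmonize(sim.network,
                   {"tpm": sim.tpm, "counts": sim.counts, "cna": sim.cna},
                   sim.clinical)
curv = curvature_matrix(cohort, kind="rna")     # edges x samples
X = feature_matrix(curv)                        # samples x edges
k, scores = select_k_silhouette(X)
labels = hierarchical_cluster(X, k)
stat, df, p = logrank_by_label(cohort.clinical, labels)
risk = assign_risk_groups(labels, cohort.clinical, mode="auto")
de = nb_two_group_test(cohort.matrices["counts"].values, risk.assignment)
sig = select_significant(de)                    # q < 0.05, |log2FC| > 3.5
```

Output on this seed:

```
cohort: 150 genes, 584 edges, 80 samples
curvature matrix: 584 edges x 80 samples, range [-1.20, 0.62]
silhouette selects k = 3 (score 0.572)
log-rank across clusters: chi2 = 6.3, df = 2, p = 4.31e-02
risk groups: {'excluded': 28, 'high': 28, 'low': 24}
significant genes (q<0.05, |log2FC|>3.5): 47 (23 over, 24 under)
```

Reading this: the silhouette criterion recovers the three planted
subtypes from curvature features alone; the clusters differ in
progression-free survival (log-rank p ≈ 0.04 at this small n); and the
high-vs-low-risk differential expression recovers 47 genes, nearly all
of them the planted strong markers of the two outcome-extreme subtypes
(25 up-shifted + 25 down-shifted at |log2FC| = 4). At the default
validation scale (300 genes, 200 samples) recovery is sharper — see the
acceptance results below.

The same workflow is available as a CLI for shell use:

```
orcnet simulate --seed 7 --out cohort/
orcnet curvature --network cohort/network.tsv --omics cohort/tpm.tsv \
       --clinical cohort/clinical.tsv --kind rna --out curv.tsv
orcnet cluster --curvature curv.tsv --k auto --out labels.tsv
orcnet survive --labels labels.tsv --clinical cohort/clinical.tsv --out surv/
orcnet diffexp --counts cohort/counts.tsv --groups surv/risk.tsv --out de/
orcnet topology --network cohort/network.tsv --curvature curv.tsv \
       --risk surv/risk.tsv --gene G042 --k 2 --out nbhd.json
orcnet run --config pipeline.yaml          # all of the above, with caching
```

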