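# Methods

## The model

`orcnet` treats a cohort of tumour samples as a family of weighted graphs
that share one topology. The topology is a curated gene-product
interaction network (an HPRD-style edge list over gene symbols); what
varies between samples is the weighting, derived from that sample's
omics profile.

**Per-sample graph weighting.** For a sample with per-gene values
`r_k > 0` (RNA: `r = log2(TPM + 1) + eps`; copy number: copies floored
at 0 plus `eps`), each node `i` defines a random-walk step to its
neighbours with probabilities

    p_ij = r_j / sum_{k in N(i)} r_k        (j adjacent to i, else 0)

These transition probabilities are asymmetric, so the edge weight is the
symmetrized `w_ij = (p_ij + p_ji) / 2`, and the edge length is
`l_ij = 1 / sqrt(w_ij)`: strongly coupled genes sit close together,
weakly coupled genes far apart.

**Ollivier-Ricci curvature (ORC).** For every edge `(i, j)`,

    kappa(i, j) = 1 - W1(mu_i, mu_j) / d(i, j)

where `mu_i` is the neighbour measure of `i` (mass `p_ik` on each
neighbour `k`, none on `i` itself), `W1` is the Wasserstein-1 distance
between the two measures under the graph's shortest-path metric, and
`d(i, j)` is the weighted shortest-path distance between the endpoints
(which for adjacent nodes can be shorter than the direct edge when a
bypass exists). `kappa <= 1` always; `kappa = 1` only when the two
measures coincide. Positive curvature marks redundantly connected,
hub-like edges whose traffic survives perturbation; negative curvature
marks bottleneck, bridge-like edges. On uniform node values a triangle
has `kappa = 1/2` on every edge and a two-edge path has `kappa = 0` —
both derivable by hand from the three formulas above, and both enforced
in the test suite.

**Downstream analysis.** The edges-by-samples curvature matrix is the
patient feature space. Samples are clustered by Ward-linkage
agglomerative clustering on Euclidean distances, with the number of
clusters selected by mean silhouette over k = 2..12 (ties to the
smaller k; singleton clusters contribute silhouette 0). Clusters are
merged into high/low-risk groups either by an explicit mapping or
automatically by ranking clusters on median Kaplan-Meier survival
(worst tertile high, best tertile low, middle excluded). Risk groups
are then compared by log-rank tests, a per-gene univariate Cox screen
(Efron ties; covariate = per-gene z-score of log2(TPM+1), so
coefficients are log-hazard per SD), negative-binomial differential
expression on read counts, hypergeometric over-representation against
user-supplied GMT gene sets, and per-edge robustness deltas (median
curvature in the high-risk group minus the low-risk group; positive =
robust, negative = fragile). Genes are classified by interactome degree:
singleton (degree 1), hub (degree strictly greater than twice the mean
degree — with mean degree 8.4 that reproduces a ">16 connections" hub
cut), bridge (everything between).

## Numerical choices

- **Exact transport, no regularization.** W1 is solved as an exact
  linear program (HiGHS via scipy). Supports are node neighbourhoods
  (median degree ~8), so exact solves are cheap; entropic approximations
  would trade reproducibility for nothing here. Mass shared by the two
  measures at the same node is cancelled before the solve — valid for a
  metric ground cost, where optimal plans never move shared mass — and
  independent per-edge LPs are batched into block-diagonal solves
  (32 per call) purely to amortize solver overhead; batching provably
  cannot change the per-block optima.
- **Ground metric.** The transport ground distance is the full-graph
  weighted shortest-path metric — the same `d` that appears in the
  curvature denominator. A `ground_metric="hop"` switch exists for
  sensitivity analysis.
- **Brute-force oracle.** An independent reference implementation
  recomputes curvature from scratch on small graphs: shortest paths by
  exhaustive simple-path enumeration, transport by enumerating every
  basis of the transportation polytope (constraint matrices are totally
  unimodular, so singular bases are detected exactly by |det| < 1/2).
  The production path must agree with it to 1e-8 on hundreds of random
  weighted graphs; the oracle harness caps degrees at 4 so that basis
  enumeration (C(16,7) = 11,440 candidate bases per edge) stays
  tractable.
- **Zero-expression floor.** `eps = 0.01` (configurable) keeps node
  values strictly positive so neighbour measures and edge lengths are
  always defined; at eps = 0 an unexpressed gene would produce
  zero-probability transitions and infinite lengths.
- **Edge order.** Lexicographic by (min endpoint, max endpoint)
  everywhere, so curvature matrices are bit-reproducible and columns
  from different runs align.
- **Tie-breaks.** Equal-size connected components: the one containing
  the lexicographically smallest gene symbol. Equal silhouette: the
  smaller k. Even-size medians: midpoint of the central order
  statistics.
- **Differential expression.** A deliberately transparent
  negative-binomial pipeline: median-of-ratios size factors, gene-wise
  method-of-moments dispersion (floored at 1e-8) from within-group
  residuals on normalized counts, and a Wald test on the group
  coefficient of an NB log-linear model with log size factors as offset
  (statsmodels GLM). No dispersion shrinkage and no independent
  filtering — calibration is verified by simulation instead (null
  type-I error within [0.03, 0.08] at dispersion 0.2). Genes with zero
  counts everywhere are excluded and reported; genes zero in one group
  get their fold change from a 0.5 pseudocount on normalized means.
  The published significance filter is applied with strict
  inequalities: BH q < 0.05 and |log2FC| > 3.5.
- **Hyperdiploidy.** A sample is flagged when more than two of
  chromosomes 3, 5, 7, 9, 11, 15, 19, 21 carry gains covering more than
  60% of the chromosome's segmented length (both thresholds strict).

## The synthetic cohort generator

Real myeloma cohorts with matched interactome coverage are access
controlled, so validation runs on simulated cohorts whose ground truth
is planted and recorded. The generator emulates:

- **Interactome**: Barabasi-Albert preferential attachment with m = 4
  (mean degree `2m(n-m)/n`, about 8 at large n, with a heavy-tailed hub
  degree distribution), or a configuration-model alternative with a
  target mean degree. Default 300 genes.
- **Expression**: negative-binomial counts (gamma-Poisson, dispersion
  0.2 — a typical bulk RNA-seq scale) with expected value proportional
  to `baseline_g x 2^shift x (copies/2)^gamma`, renormalized per sample
  so the expected total equals the library size (sequencing depth fixes
  totals, so abundances are inherently relative; count-level fold
  changes survive because median-of-ratios size factors absorb
  per-sample scalars). Library sizes are log-normal around 3e5;
  baselines are log-normal over ~4 decades. TPM
  is counts normalized to 1e6 per sample with unit gene lengths (so TPM
  = CPM; transcript-length effects belong to upstream quantification and
  are out of scope). Two planted layers: per-subtype modules (10% of
  genes, +2.0 log2 within the owning subtype — broad clustering signal)
  and per-subtype marker sets (25 genes, +4.0 log2), mimicking the
  hallmark overexpression that defines real myeloma subtypes (CCND1
  under t(11;14), MMSET under t(4;14), MAF translocations). Markers are
  symmetric across subtypes on purpose: concentrating the strong genes
  in one subtype makes the best silhouette split two-way instead of
  K-way, which no longer reflects the planted design.
- **Copy number**: subtype 1 is hyperdiploid — +1 copy over 70% of five
  of the canonical gain chromosomes (3, 5, 7, 9, 11) — and other samples
  carry occasional focal arm losses; genes map to 22 chromosomes in
  contiguous blocks, and both gene-level copies and a segment table are
  emitted so the hyperdiploidy annotator is testable end to end. Copy
  number couples to expression through `(copies/2)^gamma`, gamma = 1.
- **Survival**: exponential times with log-hazard
  `log(lambda_0) + beta_subtype + sum_g beta_g z_g`; baseline median
  PFS 3 years, subtype hazard ratios (1, 1.7, 3), and 4 prognostic genes
  at 0.40 log-hazard per SD of log2(TPM+1) — hazard ratio ~1.5 per SD,
  the scale reported for univariately prognostic genes in myeloma
  cohorts. Four genes rather than more is a deliberate cohort-scale
  choice: the summed gene effects act as patient-level frailty that
  dilutes the subtype survival contrast, and omitted-covariate
  attenuation shrinks each gene's marginal coefficient, so at 200
  samples a larger or stronger planted panel cannot be simultaneously
  recoverable per gene and subordinate to the subtype signal. The
  gene-level z-scores are centred within subtype before entering the
  hazard so gene effects stay orthogonal to subtype effects and the
  planted subtype hazard ratios are exact. Censoring is administrative
  with staggered follow-up, uniform on (5, 10) years, giving roughly
  15-20% censoring.

Everything is driven by a single integer seed; identical configurations
produce byte-identical output files.

**What passing tests do and do not show.** The generator produces
independent NB noise per gene, clean subtype structure, exponential
hazards and a fixed true interactome. Real cohorts add correlated
expression programs, batch effects, mixed censoring mechanisms,
interactome false positives/negatives, and subtype structure far less
separable than planted modules — so recovery on these simulations
validates the machinery (the curvature computation, the statistical
calibration, the plumbing between stages), not the clinical
discovery claims, which require the original gated data.

## Problem sizes

The standard validation cohort is 300 genes x 200 samples x 3 subtypes
(about 1,200 interactome edges, i.e. ~240,000 exact transport solves per
curvature matrix, a few minutes on one core). The oracle sweep uses 200
random graphs of up to 8 nodes. Calibration harnesses use 20 null
cohorts of 500 genes (NB test) and 50 null cohorts of 200 samples
(Cox). These sizes make the whole validation suite run at desk scale
while keeping every statistical check adequately powered.

## Known limitations

- All-pairs shortest paths are held densely per sample; fine into the
  low thousands of genes, but a full 8,000-node interactome at cohort
  scale would want a sparser distance strategy and parallelism over
  samples (the per-sample computation is embarrassingly parallel and
  deterministic either way).
- The DE stage is a documented, calibrated NB substitute, not a DESeq2
  re-implementation: no dispersion shrinkage, no outlier refitting, no
  independent filtering. Externally produced DE tables can be dropped
  in via the CLI where exact DESeq2 numbers matter.
- Auto risk grouping ranks clusters by median KM survival and needs the
  medians to be finite and distinct; heavily censored cohorts where
  medians are unreached should use the manual mapping path.
- Gene identifiers are opaque case-sensitive strings; no alias
  harmonization is attempted.
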