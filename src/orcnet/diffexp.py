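"""Differential expression between risk groups and gene-set enrichment.

A self-contained negative-binomial two-group test on read counts:
median-of-ratios size factors, gene-wise method-of-moments dispersion,
and a Wald test on the group coefficient of an NB log-linear model (no
dispersion shrinkage, no independent filtering). Downstream, the
published significance filter (BH q < 0.05 and |log2FC| > 3.5, strict
inequalities) and a hypergeometric over-representation test against
user-supplied gene sets.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .survival import bh_fdr

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors per sample.

    factor_s = median over all-positive genes of count_gs / geometric
    mean of gene g across samples. Raises when no gene is positive in
    every sample.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene is positive in every sample; consider a pseudocount")
    logc = np.log(arr[allpos])
    log_geomean = logc.mean(axis=1, keepdims=True)
    ratios = np.exp(logc - log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def _mom_dispersion(y: np.ndarray, group_means: np.ndarray, n_params: int) -> float:
    """Method-of-moments NB dispersion from within-group residuals.

    Solves var = mu + alpha mu^2 with the pooled residual variance and
    mean; floored at DISPERSION_FLOOR.
    """
    resid = y - group_means
    dof = max(len(y) - n_params, 1)
    s2 = float((resid ** 2).sum() / dof)
    mu = float(y.mean())
    if mu <= 0:
        return DISPERSION_FLOOR
    return max((s2 - mu) / mu ** 2, DISPERSION_FLOOR)


def nb_two_group_test(counts: pd.DataFrame, groups: pd.Series,
                      min_group_size: int = 3) -> pd.DataFrame:
    """Negative-binomial Wald test of high vs low risk group per gene.

    ``groups`` maps sample -> 'high'/'low' (other values ignored). For
    each gene, counts are modelled as NB with log link, a group indicator
    (high = 1) and log size factors as offset; the gene-wise dispersion
    comes from a method-of-moments fit on normalized counts. Returns a
    frame with baseMean, log2FoldChange (high vs low), pvalue, qvalue,
    direction, status; genes with all-zero counts are excluded and
    reported in ``result.attrs['all_zero']``.
    """
    groups = groups[groups.isin(["high", "low"])]
    samples = [s for s in counts.columns if s in groups.index]
    g = groups.loc[samples]
    n_high = int((g == "high").sum())
    n_low = int((g == "low").sum())
    if n_high < min_group_size or n_low < min_group_size:
        raise ValueError(f"each group needs >= {min_group_size} samples "
                         f"(high={n_high}, low={n_low})")
    sub = counts[samples]
    arr = sub.to_numpy(dtype=float)
    all_zero = arr.sum(axis=1) == 0
    if all_zero.any():
        logger.warning("excluding %d gene(s) with all-zero counts", int(all_zero.sum()))
    sub = sub.loc[~all_zero]
    arr = arr[~all_zero]

    sf = size_factors(sub).to_numpy()
    norm = arr / sf
    is_high = (g == "high").to_numpy()
    design = sm.add_constant(is_high.astype(float))
    offset = np.log(sf)

    base_mean = norm.mean(axis=1)
    mean_high = norm[:, is_high].mean(axis=1)
    mean_low = norm[:, ~is_high].mean(axis=1)

    rows = []
    for i, gene in enumerate(sub.index):
        y = arr[i]
        mu_groups = np.where(is_high, norm[i, is_high].mean(), norm[i, ~is_high].mean())
        alpha = _mom_dispersion(norm[i], mu_groups, n_params=2)
        zero_group = mean_high[i] == 0 or mean_low[i] == 0
        lfc = np.log2((mean_high[i] + 0.5) / (mean_low[i] + 0.5)) if zero_group else np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(y, design, family=sm.families.NegativeBinomial(alpha=alpha),
                               offset=offset)
                fit = model.fit()
            coef = float(fit.params[1])
            p = float(fit.pvalues[1])
            if not zero_group:
                lfc = coef / np.log(2.0)
            status = "ok"
        except Exception:
            p = np.nan
            if not zero_group:
                lfc = np.log2((mean_high[i] + 0.5) / (mean_low[i] + 0.5))
            status = "failed"
        rows.append((gene, base_mean[i], lfc, p, status))

    table = pd.DataFrame(rows, columns=["gene", "baseMean", "log2FoldChange",
                                        "pvalue", "status"])
    ok = table["pvalue"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(table.loc[ok, "pvalue"].to_numpy())
    table["qvalue"] = q
    table["direction"] = np.where(table["log2FoldChange"] > 0, "over", "under")
    table = table.set_index("gene", drop=False)
    table.attrs["all_zero"] = list(counts.index[all_zero])
    table.attrs["n_high"] = n_high
    table.attrs["n_low"] = n_low
    return table


def select_significant(de: pd.DataFrame, q_max: float = 0.05,
                       lfc_min: float = 3.5) -> pd.DataFrame:
    """Apply the published filter: q < q_max and |log2FC| > lfc_min, both strict."""
    if de.empty:
        raise ValueError("empty DE table")
    mask = (de["qvalue"] < q_max) & (de["log2FoldChange"].abs() > lfc_min)
    return de.loc[mask.fillna(False)].copy()


def hypergeom_enrichment(query: list[str], sets: dict[str, list[str]],
                         universe: list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe; the p-value is the upper
    tail P(overlap >= observed) and q-values are BH-corrected across
    sets. Returns one row per set with the overlapping genes.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    if not query_set <= universe_set:
        raise ValueError("query genes must be a subset of the universe")
    M = len(universe_set)
    N = len(query_set)
    rows = []
    for name, genes in sets.items():
        members = set(genes) & universe_set
        K = len(members)
        overlap = sorted(members & query_set)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append((name, k, K, M, N, p, ",".join(overlap)))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "universe_size",
                                        "query_size", "pvalue", "overlap_genes"])
    table["qvalue"] = bh_fdr(table["pvalue"].to_numpy()) if len(table) else []
    return table.set_index("set", drop=False)
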