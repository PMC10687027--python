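"""Survival analysis: Kaplan-Meier, log-rank, BH-FDR, Cox models.

Thin, validated wrappers around lifelines (KM estimator, log-rank test,
Cox proportional hazards with Efron tie handling) and statsmodels
(Benjamini-Hochberg step-up), plus the per-gene univariate Cox loop used
for prognostic gene screening. Gene covariates enter the univariate Cox
model as per-gene z-scores of log2(TPM+1), so coefficients are
log-hazard per standard deviation of log expression; a hazard ratio
above 1 marks a detrimental gene (shorter progression-free survival).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the sorted distinct observed times, ``survival`` the
    step-function values S(t) immediately after each time, ``at_risk``
    the risk-set sizes just before each time, ``censor_times`` the times
    of censored observations. S(0) = 1 and S is non-increasing.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    median_survival_time: float

    def survival_at(self, t: float) -> float:
        if t < 0:
            raise ValueError("time must be nonnegative")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_["KM_estimate"]
    # drop the t=0 anchor row; keep event/censor times
    t = sf.index.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    keep = t > 0
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    med = kmf.median_survival_time_
    return KMCurve(times=t[keep], survival=s[keep], at_risk=at_risk[keep],
                   censor_times=np.sort(times[events == 0]),
                   median_survival_time=float(med))


def logrank_test(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, int, float]:
    """Log-rank test across two or more groups.

    ``groups`` is a list of (times, events) arrays. Returns the
    chi-square statistic, its degrees of freedom (groups - 1) and the
    p-value. Identical groups give statistic 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {g} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    res = multivariate_logrank_test(np.concatenate(times), np.concatenate(labels),
                                    np.concatenate(events))
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def logrank_by_label(clinical: pd.DataFrame, labels: pd.Series) -> tuple[float, int, float]:
    """Global log-rank across the groups defined by ``labels`` (sample-indexed)."""
    common = clinical.index.intersection(labels.index)
    groups = []
    for lab in sorted(labels.loc[common].unique()):
        samples = labels.loc[common][labels.loc[common] == lab].index
        sub = clinical.loc[samples]
        groups.append((sub["pfs_time"].to_numpy(), sub["event"].to_numpy()))
    return logrank_test(groups)


def logrank_pairwise(clinical: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """All pairwise log-rank tests between label groups, BH-corrected."""
    common = clinical.index.intersection(labels.index)
    lab = labels.loc[common]
    groups = {g: clinical.loc[lab[lab == g].index] for g in sorted(lab.unique())}
    if len(groups) < 2:
        raise ValueError("pairwise log-rank needs at least two groups")
    rows = []
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            stat, _, p = logrank_test([
                (groups[a]["pfs_time"].to_numpy(), groups[a]["event"].to_numpy()),
                (groups[b]["pfs_time"].to_numpy(), groups[b]["event"].to_numpy()),
            ])
            rows.append((a, b, stat, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CoxResult:
    """Per-gene univariate Cox screen results.

    ``table`` columns: gene, coef (log-hazard per SD of log2(TPM+1)),
    hazard_ratio, se, p, q, status ('ok', 'constant', 'failed').
    """

    table: pd.DataFrame
    covariate_scale: str = "zscore_log2_tpm_plus_1"


def _prepare_cox_frame(values: np.ndarray, times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"x": values, "time": times, "event": events})


def cox_univariate(expression: pd.DataFrame, clinical: pd.DataFrame,
                   transform: str = "zscore_log2") -> CoxResult:
    """Univariate Cox proportional-hazards screen over genes.

    ``expression`` is genes x samples TPM. Each gene is transformed to a
    per-gene z-score of log2(TPM+1) (``transform='zscore_log2'``), fitted
    in its own Cox model against PFS with Efron tie handling, and the
    Wald p-values are BH-corrected across the genes that converged.
    Constant covariates are flagged and skipped.
    """
    samples = [s for s in clinical["sample"] if s in expression.columns]
    if not samples:
        raise ValueError("no overlap between expression columns and clinical samples")
    clin = clinical.loc[samples]
    times = clin["pfs_time"].to_numpy(dtype=float)
    events = clin["event"].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ValueError("no events observed")

    expr = expression[samples].to_numpy(dtype=float)
    if transform == "zscore_log2":
        expr = np.log2(expr + 1.0)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    mean = expr.mean(axis=1, keepdims=True)
    sd = expr.std(axis=1, ddof=0, keepdims=True)

    rows = []
    for g, gene in enumerate(expression.index):
        if sd[g, 0] == 0:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, "constant"))
            continue
        z = (expr[g] - mean[g, 0]) / sd[g, 0]
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(_prepare_cox_frame(z, times, events),
                        duration_col="time", event_col="event")
            s = cph.summary.loc["x"]
            rows.append((gene, float(s["coef"]), float(np.exp(s["coef"])),
                         float(s["se(coef)"]), float(s["p"]), "ok"))
        except Exception:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, "failed"))
    table = pd.DataFrame(rows, columns=["gene", "coef", "hazard_ratio", "se", "p", "status"])
    ok = table["status"] == "ok"
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(table.loc[ok, "p"].to_numpy())
    table["q"] = q
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("univariate Cox: %d gene(s) skipped or failed", n_bad)
    return CoxResult(table=table.set_index("gene", drop=False))


def cox_multivariable(covariates: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Joint Cox model over a samples x covariates frame; returns the summary."""
    samples = [s for s in clinical["sample"] if s in covariates.index]
    if not samples:
        raise ValueError("no overlap between covariates and clinical samples")
    clin = clinical.loc[samples]
    df = covariates.loc[samples].astype(float).copy()
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant covariate(s): %s", constant)
        df = df.drop(columns=constant)
    if df.empty:
        raise ValueError("no non-constant covariates")
    df["time"] = clin["pfs_time"].to_numpy(dtype=float)
    df["event"] = clin["event"].to_numpy(dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return cph.summary.copy()


def km_by_group(clinical: pd.DataFrame, labels: pd.Series) -> dict[str, KMCurve]:
    """KM curve per group label (labels indexed by sample)."""
    out: dict[str, KMCurve] = {}
    common = clinical.index.intersection(labels.index)
    for lab in sorted(labels.loc[common].unique()):
        samples = labels.loc[common][labels.loc[common] == lab].index
        sub = clinical.loc[samples]
        out[str(lab)] = km_estimate(sub["pfs_time"].to_numpy(), sub["event"].to_numpy())
    return out
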