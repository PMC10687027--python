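import numpy as np
import pandas as pd
import pytest

from orcnet.survival import (bh_fdr, cox_multivariable, cox_univariate,
                             km_estimate, logrank_pairwise, logrank_test)


class TestKMEstimate:
    def test_two_events(self):
        curve = km_estimate([1.0, 2.0], [1, 1])
        assert curve.survival_at(0.5) == pytest.approx(1.0)
        assert curve.survival_at(1.0) == pytest.approx(0.5)
        assert curve.survival_at(2.0) == pytest.approx(0.0)

    def test_all_censored_flat(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (curve.survival == 1.0).all()

    def test_event_then_censor_never_reaches_zero(self):
        curve = km_estimate([1.0, 2.0], [1, 0])
        assert curve.survival_at(1.5) == pytest.approx(0.5)
        assert curve.survival[-1] > 0.0

    def test_non_increasing(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, size=50)
        e = rng.integers(0, 2, size=50)
        curve = km_estimate(t, e)
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_p_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        stat, df, p = logrank_test([(t, e), (t, e)])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_k_identical_groups_p_one(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 1])
        stat, df, p = logrank_test([(t, e)] * 4)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_planted_hazard_ratio_detected(self):
        """HR 3, n=100/arm: significant in nearly all replicates."""
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(20):
            t1 = rng.exponential(1.0, size=100)
            t2 = rng.exponential(1 / 3, size=100)
            e = np.ones(100, dtype=int)
            _, _, p = logrank_test([(t1, e), (t2, e)])
            hits += p < 0.01
        assert hits >= 18

    def test_matches_permutation_null(self):
        """Asymptotic p vs an independent permutation-null estimate."""
        rng = np.random.default_rng(42)
        n = 12
        t1 = rng.exponential(1.0, size=n)
        t2 = rng.exponential(0.5, size=n)
        e1 = (rng.uniform(size=n) > 0.2).astype(int)
        e2 = (rng.uniform(size=n) > 0.2).astype(int)
        stat, _, p = logrank_test([(t1, e1), (t2, e2)])

        times = np.concatenate([t1, t2])
        events = np.concatenate([e1, e2])
        count = 0
        n_perm = 1500
        for _ in range(n_perm):
            perm = rng.permutation(2 * n)
            g1, g2 = perm[:n], perm[n:]
            s, _, _ = logrank_test([(times[g1], events[g1]),
                                    (times[g2], events[g2])])
            count += s >= stat - 1e-12
        p_perm = count / n_perm
        # Monte-Carlo SE ~ 0.009 plus chi-square approximation error at n=24
        assert p == pytest.approx(p_perm, abs=0.05)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([(np.array([1.0]), np.array([1]))])

    def test_pairwise_tests_enumerate_all_pairs(self):
        rng = np.random.default_rng(55)
        n = 60
        labels = pd.Series(rng.integers(1, 4, size=n),
                           index=[f"s{k}" for k in range(n)])
        clinical = pd.DataFrame({
            "sample": labels.index,
            "pfs_time": rng.exponential(2.0, size=n) + 1e-3,
            "event": rng.integers(0, 2, size=n),
        }).set_index("sample", drop=False)
        out = logrank_pairwise(clinical, labels)
        assert len(out) == 3  # C(3,2)
        assert (out["q"] >= out["p"] - 1e-12).all()
        np.testing.assert_allclose(out["q"], bh_fdr(out["p"].to_numpy()))


class TestBhFdr:
    def test_hand_worked_example(self):
        # p*m/rank: (.03, .03, .03) after cumulative min from the right
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_direct_step_up_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            m = len(p)
            order = np.argsort(p)
            q_sorted = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        assert (bh_fdr(p) >= p - 1e-12).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def make_cohort(rng, n, beta=0.0, n_genes=1):
    """Exponential survival with optional per-gene log-hazard on z-scores."""
    expr = rng.lognormal(3.0, 1.0, size=(n_genes, n))
    logtpm = np.log2(expr + 1)
    z = (logtpm - logtpm.mean(axis=1, keepdims=True)) / logtpm.std(axis=1, keepdims=True)
    lin = beta * z.sum(axis=0)
    t_event = rng.exponential(np.exp(-lin) / 0.5)
    t_cens = rng.uniform(0, 6.0, size=n)
    samples = [f"s{k}" for k in range(n)]
    clinical = pd.DataFrame({
        "sample": samples,
        "pfs_time": np.maximum(np.minimum(t_event, t_cens), 1e-4),
        "event": (t_event <= t_cens).astype(int),
    }).set_index("sample", drop=False)
    genes = [f"g{k}" for k in range(n_genes)]
    return pd.DataFrame(expr, index=genes, columns=samples), clinical


class TestCoxUnivariate:
    def test_null_type_one_error_calibrated(self):
        """Covariates independent of survival: ~5% false positives."""
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(25):
            expr, clinical = make_cohort(rng, 200, beta=0.0, n_genes=4)
            res = cox_univariate(expr, clinical)
            pvals.extend(res.table["p"].tolist())
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.01 <= rate <= 0.10

    def test_planted_effect_recovered(self):
        """beta=0.7 per SD, n=300: mean estimate within +-0.15."""
        rng = np.random.default_rng(22)
        coefs = []
        for _ in range(25):
            expr, clinical = make_cohort(rng, 300, beta=0.7, n_genes=1)
            res = cox_univariate(expr, clinical)
            coefs.append(res.table["coef"].iloc[0])
        assert np.mean(coefs) == pytest.approx(0.7, abs=0.15)

    def test_positive_beta_means_hazard_ratio_above_one(self):
        rng = np.random.default_rng(23)
        expr, clinical = make_cohort(rng, 300, beta=0.7, n_genes=1)
        res = cox_univariate(expr, clinical)
        assert res.table["hazard_ratio"].iloc[0] > 1.0
        assert res.table["hazard_ratio"].iloc[0] == pytest.approx(
            np.exp(res.table["coef"].iloc[0]))

    def test_duplicated_gene_identical_coefficients(self):
        rng = np.random.default_rng(24)
        expr, clinical = make_cohort(rng, 100, beta=0.5, n_genes=1)
        expr2 = pd.concat([expr, expr.rename(index={"g0": "g0_copy"})])
        res = cox_univariate(expr2, clinical)
        assert res.table.loc["g0", "coef"] == pytest.approx(
            res.table.loc["g0_copy", "coef"])

    def test_constant_gene_flagged(self):
        rng = np.random.default_rng(25)
        expr, clinical = make_cohort(rng, 50, n_genes=2)
        expr.iloc[1] = 7.0
        res = cox_univariate(expr, clinical)
        assert res.table["status"].iloc[1] == "constant"
        assert np.isnan(res.table["coef"].iloc[1])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(26)
        expr, clinical = make_cohort(rng, 120, beta=0.3, n_genes=10)
        res = cox_univariate(expr, clinical)
        ok = res.table["status"] == "ok"
        assert (res.table.loc[ok, "q"] >= res.table.loc[ok, "p"] - 1e-12).all()


class TestCoxMultivariable:
    def test_joint_fit_recovers_signs(self):
        rng = np.random.default_rng(30)
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        t_event = rng.exponential(np.exp(-(0.8 * x1 - 0.5 * x2)) / 0.4)
        clinical = pd.DataFrame({
            "sample": [f"s{k}" for k in range(n)],
            "pfs_time": np.maximum(t_event, 1e-4),
            "event": np.ones(n, dtype=int),
        }).set_index("sample", drop=False)
        cov = pd.DataFrame({"x1": x1, "x2": x2}, index=clinical.index)
        summary = cox_multivariable(cov, clinical)
        assert summary.loc["x1", "coef"] > 0
        assert summary.loc["x2", "coef"] < 0
        assert summary.loc["x1", "coef"] == pytest.approx(0.8, abs=0.2)
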