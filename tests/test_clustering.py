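import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from orcnet.clustering import (annotate_hyperdiploidy, assign_risk_groups,
                               cluster_feature_association, feature_matrix,
                               hierarchical_cluster, select_k_silhouette)


def blobs(rng, centers, n_per, sd=1.0):
    X = np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    idx = [f"s{k}" for k in range(len(X))]
    return pd.DataFrame(X, index=idx), pd.Series(labels, index=idx)


class TestFeatureMatrix:
    def test_transpose(self):
        curv = pd.DataFrame(np.arange(6).reshape(3, 2),
                            index=["e1", "e2", "e3"], columns=["s1", "s2"])
        X = feature_matrix(curv)
        assert X.shape == (2, 3)
        assert X.loc["s2", "e3"] == 5

    def test_standardization(self):
        rng = np.random.default_rng(0)
        curv = pd.DataFrame(rng.normal(5, 2, size=(4, 10)),
                            index=list("abcd"), columns=[f"s{k}" for k in range(10)])
        X = feature_matrix(curv, standardize=True)
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=0, ddof=0), 1, atol=1e-12)

    def test_constant_edge_dropped(self, caplog):
        curv = pd.DataFrame([[1.0, 1.0], [0.2, 0.9]], index=["e1", "e2"],
                            columns=["s1", "s2"])
        with caplog.at_level("WARNING"):
            X = feature_matrix(curv, standardize=True)
        assert list(X.columns) == ["e2"]
        assert "constant" in caplog.text


class TestHierarchicalCluster:
    def test_perfect_split(self):
        rng = np.random.default_rng(1)
        X, truth = blobs(rng, [(0, 0), (100, 100)], 15)
        labels = hierarchical_cluster(X, 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self):
        X = pd.DataFrame(np.arange(8).reshape(4, 2) * 10.0, index=list("abcd"))
        labels = hierarchical_cluster(X, 4)
        assert labels.nunique() == 4

    def test_duplicated_rows_same_cluster(self):
        X = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0]], index=list("abc"))
        labels = hierarchical_cluster(X, 2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_k_too_large_errors(self):
        X = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            hierarchical_cluster(X, 4)

    def test_labels_contiguous_from_one(self):
        rng = np.random.default_rng(2)
        X, _ = blobs(rng, [(0, 0), (50, 0), (0, 50)], 10)
        labels = hierarchical_cluster(X, 3)
        assert sorted(labels.unique()) == [1, 2, 3]

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(3)
        X, _ = blobs(rng, [(0, 0), (20, 20), (40, 0)], 12, sd=2.0)
        l1 = hierarchical_cluster(X, 3)
        shuffled = X.sample(frac=1.0, random_state=7)
        l2 = hierarchical_cluster(shuffled, 3)
        assert adjusted_rand_score(l1.loc[X.index], l2.loc[X.index]) == 1.0


class TestSelectKSilhouette:
    def test_three_blobs(self):
        rng = np.random.default_rng(10)
        X, _ = blobs(rng, [(0, 0), (10, 0), (0, 10)], 30, sd=1.0)
        k, scores = select_k_silhouette(X, range(2, 7))
        assert k == 3
        assert scores[3] == max(scores.values())

    def test_two_blobs(self):
        rng = np.random.default_rng(11)
        X, _ = blobs(rng, [(0, 0), (10, 10)], 30, sd=1.0)
        k, _ = select_k_silhouette(X, range(2, 6))
        assert k == 2

    def test_empty_range_errors(self):
        X = pd.DataFrame(np.eye(5))
        with pytest.raises(ValueError, match="empty"):
            select_k_silhouette(X, [])

    def test_tie_prefers_smaller_k(self):
        # two clean blobs: k=2 wins; degenerate checks of the tie rule need
        # identical scores, so verify the ordering key directly
        scores = {2: 0.5, 3: 0.5, 4: 0.4}
        best = max(sorted(scores), key=lambda k: (scores[k], -k))
        assert best == 2


class TestAssignRiskGroups:
    @pytest.fixture
    def clinical(self):
        samples = [f"s{k}" for k in range(12)]
        # first 6 samples die fast, last 6 survive long
        times = [0.5, 0.6, 0.7, 0.5, 0.6, 0.7, 5.0, 6.0, 5.5, 6.5, 5.0, 6.0]
        return pd.DataFrame({"sample": samples, "pfs_time": times,
                             "event": [1] * 12}).set_index("sample", drop=False)

    def test_manual_mapping_verbatim(self, clinical):
        labels = pd.Series([1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6],
                           index=clinical.index, name="cluster")
        risk = assign_risk_groups(labels, clinical, mode="manual",
                                  mapping={4: "high", 6: "high", 1: "low", 3: "low"})
        assert set(risk.assignment[labels.isin([4, 6])].unique()) == {"high"}
        assert set(risk.assignment[labels.isin([1, 3])].unique()) == {"low"}
        assert set(risk.assignment[labels.isin([2, 5])].unique()) == {"excluded"}

    def test_manual_unknown_cluster_errors(self, clinical):
        labels = pd.Series([1] * 6 + [2] * 6, index=clinical.index)
        with pytest.raises(ValueError, match="unknown cluster"):
            assign_risk_groups(labels, clinical, mode="manual", mapping={9: "high"})

    def test_auto_orders_by_survival(self, clinical):
        labels = pd.Series([1] * 6 + [2] * 6, index=clinical.index)
        risk = assign_risk_groups(labels, clinical, mode="auto")
        assert set(risk.assignment[labels == 1]) == {"high"}
        assert set(risk.assignment[labels == 2]) == {"low"}

    def test_single_cluster_errors(self, clinical):
        labels = pd.Series([1] * 12, index=clinical.index)
        with pytest.raises(ValueError, match="two clusters"):
            assign_risk_groups(labels, clinical, mode="auto")


class TestAnnotateHyperdiploidy:
    def seg(self, sample, chrom, start, end, cn):
        return {"sample": sample, "chrom": chrom, "start": start,
                "end": end, "copy_state": cn}

    def test_three_listed_gains_true(self):
        rows = []
        for c in ("3", "5", "9"):
            rows.append(self.seg("s1", c, 0, 70, 3))
            rows.append(self.seg("s1", c, 70, 100, 2))
        flags = annotate_hyperdiploidy(pd.DataFrame(rows))
        assert flags["s1"]

    def test_two_gains_insufficient(self):
        rows = []
        for c in ("3", "5"):
            rows.append(self.seg("s1", c, 0, 70, 3))
            rows.append(self.seg("s1", c, 70, 100, 2))
        rows.append(self.seg("s1", "9", 0, 100, 2))
        assert not annotate_hyperdiploidy(pd.DataFrame(rows))["s1"]

    def test_unlisted_chromosomes_do_not_count(self):
        rows = []
        for c in ("1", "2", "4"):
            rows.append(self.seg("s1", c, 0, 70, 3))
            rows.append(self.seg("s1", c, 70, 100, 2))
        assert not annotate_hyperdiploidy(pd.DataFrame(rows))["s1"]

    def test_sixty_percent_boundary_strict(self):
        rows = []
        for c in ("3", "5", "9"):
            rows.append(self.seg("s1", c, 0, 60, 3))   # exactly 60%: not enough
            rows.append(self.seg("s1", c, 60, 100, 2))
        assert not annotate_hyperdiploidy(pd.DataFrame(rows))["s1"]

    def test_chr_prefix_accepted(self):
        rows = []
        for c in ("chr3", "chr5", "chr9"):
            rows.append(self.seg("s1", c, 0, 70, 3))
            rows.append(self.seg("s1", c, 70, 100, 2))
        assert annotate_hyperdiploidy(pd.DataFrame(rows))["s1"]

    def test_unknown_chromosome_ignored_with_warning(self, caplog):
        rows = [self.seg("s1", "weird", 0, 100, 3),
                self.seg("s1", "3", 0, 100, 2)]
        with caplog.at_level("WARNING"):
            flags = annotate_hyperdiploidy(pd.DataFrame(rows))
        assert not flags["s1"]
        assert "unknown chromosome" in caplog.text


class TestClusterFeatureAssociation:
    def test_perfect_separation_exact_p(self):
        # table [[5,0],[0,5]]: two-sided Fisher p = 2 / C(10,5)
        assign = pd.Series([1] * 5 + [2] * 5, index=[f"s{k}" for k in range(10)])
        feature = pd.Series([True] * 5 + [False] * 5, index=assign.index)
        _, p = cluster_feature_association(assign, feature, cluster=1)
        assert p == pytest.approx(2 / comb(10, 5, exact=True))
        assert p == pytest.approx(1 / 126)

    def test_independent_feature_p_one(self):
        assign = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=[f"s{k}" for k in range(8)])
        feature = pd.Series([True, True, False, False] * 2, index=assign.index)
        _, p = cluster_feature_association(assign, feature, cluster=1)
        assert p == pytest.approx(1.0)

    def test_empty_cluster_errors(self):
        assign = pd.Series([1, 1], index=["a", "b"])
        feature = pd.Series([True, False], index=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            cluster_feature_association(assign, feature, cluster=9)

    def test_degenerate_table_flagged(self):
        assign = pd.Series([1, 1, 2, 2], index=list("abcd"))
        feature = pd.Series([True] * 4, index=list("abcd"))
        oddsratio, p = cluster_feature_association(assign, feature, cluster=1)
        assert p == 1.0 and np.isnan(oddsratio)
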