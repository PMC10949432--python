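"""Thresholding, explained variance, activity clustering, and DIMA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from modulonkit.imodulons import (
    IModulon,
    correlate_and_cluster_imodulons,
    detect_single_gene,
    differential_activity,
    explained_variance,
    extract_imodulons,
    fit_replicate_null,
    threshold_gene_weights,
)


def planted_weights(n_bulk=200, outliers=(6.0, -6.5, 7.0, 8.0, -5.5), seed=0):
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 0.5, n_bulk + len(outliers))
    w[: len(outliers)] = outliers
    names = [f"g{i}" for i in range(len(w))]
    return pd.Series(w, index=names), set(names[: len(outliers)])


class TestThreshold:
    def test_planted_outliers_recovered(self):
        weights, planted = planted_weights()
        threshold, members = threshold_gene_weights(weights)
        assert members == planted
        assert all(abs(weights[g]) > threshold for g in members)

    def test_gaussian_weights_give_empty_set(self):
        rng = np.random.default_rng(1)
        weights = pd.Series(rng.normal(0, 1, 300),
                            index=[f"g{i}" for i in range(300)])
        _, members = threshold_gene_weights(weights)
        assert members == set()

    def test_sign_flip_invariance(self):
        weights, _ = planted_weights()
        t1, m1 = threshold_gene_weights(weights)
        t2, m2 = threshold_gene_weights(-weights)
        assert m1 == m2 and t1 == pytest.approx(t2)

    def test_gene_reordering_invariance(self):
        weights, _ = planted_weights()
        shuffled = weights.sample(frac=1.0, random_state=3)
        _, m1 = threshold_gene_weights(weights)
        _, m2 = threshold_gene_weights(shuffled)
        assert m1 == m2

    def test_quantile_method(self):
        weights, planted = planted_weights()
        _, members = threshold_gene_weights(weights, method="quantile")
        assert members == planted

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            threshold_gene_weights(pd.Series(np.ones(50)))
        with pytest.raises(ValueError):
            threshold_gene_weights(pd.Series([1.0, 2.0, 3.0]))


class TestExplainedVariance:
    def test_empty_subset_is_zero(self):
        X = np.eye(4)
        M = np.eye(4)
        A = np.eye(4)
        assert explained_variance(X, M, A, subset=[]) == 0.0

    def test_noiseless_full_rank(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(50, 3))
        A = rng.normal(size=(3, 20))
        X = M @ A
        assert explained_variance(X, M, A) >= 0.999

    def test_toy_matches_brute_force(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 4))
        M = rng.normal(size=(4, 2))
        A = rng.normal(size=(2, 4))
        expected = 1 - np.sum((X - M[:, :1] @ A[:1]) ** 2) / np.sum(X**2)
        assert explained_variance(X, M, A, subset=[0]) == pytest.approx(expected)

    def test_subset_overlap_inequality(self):
        # singleton EVs sum <= union EV <= 1 for orthogonal-ish components
        rng = np.random.default_rng(4)
        M = np.linalg.qr(rng.normal(size=(30, 3)))[0]
        A = rng.normal(size=(3, 15))
        X = M @ A + 0.01 * rng.normal(size=(30, 15))
        singles = sum(explained_variance(X, M, A, subset=[i]) for i in range(3))
        union = explained_variance(X, M, A)
        assert singles <= union + 1e-9 <= 1 + 1e-9

    def test_zero_matrix_error(self):
        with pytest.raises(ValueError):
            explained_variance(np.zeros((3, 3)), np.eye(3), np.eye(3))


class TestSingleGene:
    def test_one_member_true(self):
        weights, _ = planted_weights(outliers=(9.0,))
        t, m = threshold_gene_weights(weights)
        im = IModulon("x", 0, weights, t, m)
        assert detect_single_gene(im)

    def test_many_equal_members_false(self):
        weights, _ = planted_weights(outliers=tuple([6.0] * 10))
        t, m = threshold_gene_weights(weights)
        im = IModulon("x", 0, weights, t, m)
        assert len(m) == 10 and not detect_single_gene(im)

    def test_dominant_weight_true(self):
        w = pd.Series([50.0, 3.0, 3.0] + [0.01] * 100,
                      index=[f"g{i}" for i in range(103)])
        t, m = threshold_gene_weights(w)
        im = IModulon("x", 0, w, t, m)
        assert detect_single_gene(im)

    def test_extract_categorises_single_gene(self):
        rng = np.random.default_rng(5)
        M = pd.DataFrame(rng.normal(0, 0.1, (100, 2)),
                         index=[f"g{i}" for i in range(100)])
        M.iloc[0, 0] = 10.0  # single-gene component
        M.iloc[10:20, 1] = 5.0  # multi-gene component
        imods = extract_imodulons(M)
        assert imods[0].category == "single-gene"
        assert imods[1].category != "single-gene"


class TestActivityClustering:
    def test_duplicate_row_same_cluster(self):
        rng = np.random.default_rng(6)
        A = pd.DataFrame(rng.normal(size=(3, 40)), index=["a", "b", "c"])
        A.loc["c"] = A.loc["a"]
        corr, Z, flat = correlate_and_cluster_imodulons(A)
        assert corr.loc["a", "c"] == pytest.approx(1.0)
        assert flat["a"] == flat["c"]

    def test_independent_rows_low_correlation(self):
        rng = np.random.default_rng(7)
        A = pd.DataFrame(rng.normal(size=(6, 500)))
        corr, _, _ = correlate_and_cluster_imodulons(A)
        off = corr.to_numpy()[np.triu_indices(6, k=1)]
        assert np.abs(off).mean() < 0.1

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(8)
        A = pd.DataFrame(rng.normal(size=(4, 30)))
        corr, _, _ = correlate_and_cluster_imodulons(A)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_constant_row_error_names_component(self):
        A = pd.DataFrame(np.random.default_rng(9).normal(size=(3, 20)),
                         index=["a", "flat", "c"])
        A.loc["flat"] = 2.0
        with pytest.raises(ValueError, match="flat"):
            correlate_and_cluster_imodulons(A)


class TestDima:
    @staticmethod
    def null_activities(seed, K=10, n=40, sd=0.3):
        r = np.random.default_rng(seed)
        cols = [f"s{i}" for i in range(n)]
        A = pd.DataFrame(r.normal(0, sd, (K, n)),
                         index=[f"c{i}" for i in range(K)], columns=cols)
        pairs = [(f"s{2*i}", f"s{2*i+1}") for i in range(n // 2)]
        return A, cols, pairs

    def test_identical_groups_zero_delta(self):
        A, cols, pairs = self.null_activities(0)
        res = differential_activity(A, cols[:5], cols[5:10], replicate_pairs=pairs)
        A2 = A.copy()
        A2[cols[5:10]] = A[cols[:5]].to_numpy()
        res2 = differential_activity(A2, cols[:5], cols[5:10], replicate_pairs=pairs)
        assert np.allclose(res2["delta_activity"], 0.0)
        assert not res2["significant"].any()

    def test_antisymmetric_under_group_swap(self):
        A, cols, pairs = self.null_activities(1)
        r12 = differential_activity(A, cols[:5], cols[5:10], replicate_pairs=pairs)
        r21 = differential_activity(A, cols[5:10], cols[:5], replicate_pairs=pairs)
        assert np.allclose(r12["delta_activity"], -r21["delta_activity"])

    def test_planted_shift_detected(self):
        A, cols, pairs = self.null_activities(2)
        A.loc["c0", cols[10:20]] += 3.0
        res = differential_activity(A, cols[:10], cols[10:20], replicate_pairs=pairs)
        assert bool(res.loc["c0", "significant"])

    def test_requires_null_source(self):
        A, cols, _ = self.null_activities(3)
        with pytest.raises(ValueError, match="null"):
            differential_activity(A, cols[:5], cols[5:10])

    def test_pvalues_uniform_when_null_family_matches(self):
        # Replicate pair differences drawn exactly from a signed log-normal:
        # probability-integral transform through the fitted null must be
        # uniform (KS < 0.1 at 1000 draws).
        r = np.random.default_rng(5)
        nfit, ntest = 300, 1000
        L_fit = np.exp(r.normal(-1.0, 0.9, nfit))
        L_test = np.exp(r.normal(-1.0, 0.9, ntest))
        cols = [f"f{i}_{j}" for i in range(nfit) for j in (0, 1)]
        vals = np.empty((1, 2 * nfit))
        vals[0, 0::2] = L_fit / 2
        vals[0, 1::2] = -L_fit / 2
        A = pd.DataFrame(vals, index=["c0"], columns=cols)
        pairs = [(f"f{i}_0", f"f{i}_1") for i in range(nfit)]
        mu, sig = fit_replicate_null(A, pairs)
        p = st.lognorm.sf(L_test, s=sig, scale=np.exp(mu))
        assert st.kstest(p, "uniform").statistic < 0.1
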