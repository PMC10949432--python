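"""Grouped folds, SMOTETomek oracles, elastic-net fit, CV evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from modulonkit.classifier import (
    _tomek_pairs,
    evaluate_cv,
    fit_elastic_net_logistic,
    operon_grouped_folds,
    rank_auc,
    resample_balanced,
)
from modulonkit.operons import OperonMap


def make_operon_map(n_operons, genes_per=3):
    ops = {
        f"op{i:03d}": [f"op{i:03d}_g{j}" for j in range(genes_per)]
        for i in range(n_operons)
    }
    return OperonMap(
        operons=ops, gene_to_operon={g: o for o, gs in ops.items() for g in gs}
    )


def operon_labels(op_map, positive_ops):
    return pd.Series(
        {g: int(o in positive_ops) for g, o in op_map.gene_to_operon.items()}
    )


class TestGroupedFolds:
    def test_ten_operons_five_folds_two_each(self):
        op_map = make_operon_map(10)
        labels = operon_labels(op_map, {f"op{i:03d}" for i in range(5)})
        folds = operon_grouped_folds(labels, op_map, k=5, seed=0)
        counts = pd.Series(folds).value_counts()
        assert (counts == 2).all()

    def test_partition_contract(self):
        op_map = make_operon_map(23)
        labels = operon_labels(op_map, {f"op{i:03d}" for i in range(7)})
        folds = operon_grouped_folds(labels, op_map, k=5, seed=1)
        assert set(folds) == set(op_map.operons)
        for f in range(5):
            test_ops = {o for o, ff in folds.items() if ff == f}
            train_ops = set(folds) - test_ops
            assert test_ops and not (test_ops & train_ops)

    def test_stratification_within_one_operon(self):
        op_map = make_operon_map(40)
        pos = {f"op{i:03d}" for i in range(12)}
        labels = operon_labels(op_map, pos)
        global_frac = 12 / 40
        for seed in range(50):
            folds = operon_grouped_folds(labels, op_map, k=5, seed=seed)
            for f in range(5):
                ops = [o for o, ff in folds.items() if ff == f]
                n_pos = sum(o in pos for o in ops)
                assert abs(n_pos - global_frac * len(ops)) <= 1

    def test_too_few_positive_operons(self):
        op_map = make_operon_map(10)
        labels = operon_labels(op_map, {"op000", "op001"})
        with pytest.raises(ValueError, match="smaller k"):
            operon_grouped_folds(labels, op_map, k=5, seed=0)


class TestResampling:
    def test_balanced_no_tomek_is_identity(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(10, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        Xo, yo = resample_balanced(X, y, seed=0)
        assert np.array_equal(Xo, X) and np.array_equal(yo, y)

    def test_synthetic_points_on_minority_segments(self):
        # classes far apart so no Tomek link removes any row and the
        # synthetic rows are exactly the tail of the output
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(100, 1, (10, 2))])
        y = np.array([0] * 40 + [1] * 10)
        Xo, yo, info = resample_balanced(X, y, k_neighbors=5, seed=2, return_info=True)
        assert info["tomek_pairs"] == []
        synth = Xo[len(y):]
        assert len(synth) == 30 and (yo[len(y):] == 1).all()
        for row, (a, b) in zip(synth, info["synthetic_parents"]):
            pa, pb = X[a], X[b]
            d = pb - pa
            t = float((row - pa) @ d) / float(d @ d)
            assert -1e-9 <= t <= 1 + 1e-9
            assert np.allclose(row, pa + t * d, atol=1e-9)
        # verified against brute-force neighbour lists: each parent pair is
        # within the k nearest minority neighbours of the base point
        min_idx = np.flatnonzero(y == 1)
        D = np.linalg.norm(X[min_idx][:, None] - X[min_idx][None, :], axis=2)
        np.fill_diagonal(D, np.inf)
        order = {int(min_idx[i]): [int(min_idx[j]) for j in np.argsort(D[i])[:5]]
                 for i in range(len(min_idx))}
        for a, b in info["synthetic_parents"]:
            assert b in order[a]

    def test_output_balanced_within_tomek_margin(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(1.5, 1, (12, 2))])
        y = np.array([0] * 60 + [1] * 12)
        Xo, yo, info = resample_balanced(X, y, seed=3, return_info=True)
        c = np.bincount(yo)
        assert abs(int(c[0]) - int(c[1])) <= len(info["tomek_pairs"])

    def test_tomek_pairs_match_brute_force(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (100, 3))
        y = rng.integers(0, 2, 100)
        pairs = _tomek_pairs(X, y)
        # O(n^2) oracle
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        np.fill_diagonal(D, np.inf)
        nn = D.argmin(axis=1)
        expected = sorted(
            (i, int(nn[i])) for i in range(100)
            if nn[i] > i and nn[nn[i]] == i and y[i] != y[nn[i]]
        )
        assert sorted(pairs) == expected

    def test_minority_too_small_error(self):
        X = np.random.default_rng(5).normal(size=(20, 2))
        y = np.array([0] * 16 + [1] * 4)
        with pytest.raises(ValueError, match="k_neighbors"):
            resample_balanced(X, y, k_neighbors=5)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            resample_balanced(np.ones((5, 1)), np.zeros(5))


class TestElasticNet:
    def test_separating_feature_coefficient_sign(self):
        x = np.concatenate([np.random.default_rng(0).normal(-2, 0.3, 30),
                            np.random.default_rng(1).normal(2, 0.3, 30)])
        y = np.array([0] * 30 + [1] * 30)
        model = fit_elastic_net_logistic(x, y, regularization_strength=0.1)
        assert model.coefficients[0] > 0

    def test_heavy_penalty_shrinks_coefficients(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 3))
        y = (X[:, 0] > 0).astype(int)
        loose = fit_elastic_net_logistic(X, y, regularization_strength=0.01)
        tight = fit_elastic_net_logistic(X, y, regularization_strength=1e4)
        assert np.abs(tight.coefficients).max() < 1e-2
        assert np.abs(loose.coefficients).max() > np.abs(tight.coefficients).max()

    def test_local_optimality_of_fit(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 2))
        y = (X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=80) > 0).astype(int)
        lam, l1 = 0.5, 0.5
        model = fit_elastic_net_logistic(X, y, l1_ratio=l1, regularization_strength=lam)
        Xs = model.scaler.transform(X)

        def loss(beta, b0):
            z = Xs @ beta + b0
            nll = np.mean(np.log1p(np.exp(-z * (2 * y - 1))))
            # sklearn penalises the sum of losses scaled by C; per-sample
            # average loss + lam/n * penalty matches up to a constant factor
            pen = lam / len(y) * (l1 * np.abs(beta).sum() + (1 - l1) / 2 * (beta**2).sum())
            return nll + pen

        beta_hat = model.coefficients
        b0 = float(model.model.intercept_[0])
        base = loss(beta_hat, b0)
        for _ in range(1000):
            assert base <= loss(beta_hat + rng.normal(0, 0.05, 2),
                                b0 + rng.normal(0, 0.05)) + 1e-9

    def test_nonfinite_features_error(self):
        with pytest.raises(ValueError):
            fit_elastic_net_logistic(np.array([[1.0], [np.nan], [2.0], [3.0]]),
                                     np.array([0, 0, 1, 1]))


class TestAuc:
    def test_matches_pairwise_concordance(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        if y.sum() in (0, 50):
            y[0] = 1 - y[0]
        pos = scores[y == 1]
        neg = scores[y == 0]
        conc = np.mean([
            1.0 if p > q else 0.5 if p == q else 0.0
            for p, q in itertools.product(pos, neg)
        ])
        assert rank_auc(scores, y) == pytest.approx(conc)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        scores = rng.normal(size=200)
        y = (scores + rng.normal(0, 1, 200) > 0).astype(int)
        assert rank_auc(scores, y) == pytest.approx(roc_auc_score(y, scores))

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            rank_auc(np.arange(5.0), np.ones(5))


class TestEvaluateCv:
    def test_label_identical_feature_gives_auc_one(self):
        op_map = make_operon_map(20)
        labels = operon_labels(op_map, {f"op{i:03d}" for i in range(6)})
        feats = pd.DataFrame({"f": labels.astype(float)})
        report = evaluate_cv(feats, labels, op_map, k=5, seed=0, resample=False)
        assert report.mean_auc == pytest.approx(1.0)
        assert report.passed_benchmark

    def test_resampling_counts_are_train_fold_counts(self):
        rng = np.random.default_rng(8)
        op_map = make_operon_map(30)
        pos = {f"op{i:03d}" for i in range(8)}
        labels = operon_labels(op_map, pos)
        feats = pd.DataFrame(
            {"f": labels.astype(float) * 2 + rng.normal(0, 0.5, len(labels))},
            index=labels.index,
        )
        report = evaluate_cv(feats, labels, op_map, k=5, seed=8)
        total = len(labels)
        for entry in report.resampling_summary:
            before = entry["counts_before"]
            # resampling saw the training portion only, never all genes
            assert sum(before.values()) < total
            after = entry["counts_after"]
            assert abs(after[0] - after[1]) <= 2 * entry["n_tomek_pairs"] + 1

    def test_grouped_split_bounds_leaky_estimate(self):
        """Operon-mates share features; i.i.d. gene splits leak and inflate AUC."""
        grouped_aucs, leaky_aucs = [], []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            op_map = make_operon_map(40, genes_per=5)
            pos = set(rng.choice(sorted(op_map.operons), size=12, replace=False))
            labels = operon_labels(op_map, pos)
            # weak informative feature + operon-level noise features that a
            # leaky split can memorise
            feats = {}
            for op, members in op_map.operons.items():
                signal = 0.8 * (op in pos) + rng.normal(0, 1)
                noise = rng.normal(0, 1, 3)
                for g in members:
                    feats[g] = np.concatenate([[signal], noise])
            F = pd.DataFrame.from_dict(feats, orient="index",
                                       columns=["f0", "f1", "f2", "f3"])
            grouped_aucs.append(
                evaluate_cv(F, labels, op_map, k=5, seed=seed, resample=False).mean_auc
            )
            leaky_aucs.append(
                evaluate_cv(F, labels, op_map, k=5, seed=seed, resample=False,
                            grouped=False).mean_auc
            )
        assert np.mean(grouped_aucs) <= np.mean(leaky_aucs)
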