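"""Decoding: discriminant power, stability selection, Gaussian classifier,
hardening, LDA ensemble."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from rsvpsearch._seeds import child_rng
from rsvpsearch.decoding import (
    GaussianClassifier,
    LdaEnsemble,
    discriminant_power,
    harden,
    stable_select,
)


def oracle_dp(X, y):
    """Independent discriminant-power computation: explicit scatter-matrix
    LDA direction, then plain per-feature correlations with the projection."""
    X0, X1 = X[y == 0], X[y == 1]
    m0, m1 = X0.mean(0), X1.mean(0)
    sw = np.cov(X0.T, bias=False) * (len(X0) - 1) + \
        np.cov(X1.T, bias=False) * (len(X1) - 1)
    sw = np.atleast_2d(sw)
    w = np.linalg.solve(sw, m1 - m0)
    proj = X @ w
    r2 = np.array([np.corrcoef(X[:, j], proj)[0, 1] ** 2
                   for j in range(X.shape[1])])
    return 100 * r2 / r2.sum()


class TestDiscriminantPower:
    def test_projection_axis_feature_dominates(self):
        rng = child_rng(0, "dp")
        y = np.repeat([0, 1], 100)
        X = rng.normal(size=(200, 6))
        X[:, 0] += 3 * y  # feature 0 is the discriminant axis
        dp = discriminant_power(X, y)
        assert dp.argmax() == 0
        assert np.isclose(dp.sum(), 100.0, atol=1e-6)

    def test_duplicated_feature_gets_equal_dp(self):
        rng = child_rng(1, "dp")
        y = np.repeat([0, 1], 50)
        base = rng.normal(size=(100, 3))
        base[:, 0] += 2 * y
        X = np.column_stack([base, base[:, 0]])
        dp = discriminant_power(X, y)
        assert np.isclose(dp[0], dp[3], atol=1e-9)

    @pytest.mark.parametrize("n_features", [2, 3, 5])
    def test_matches_independent_oracle(self, n_features):
        rng = child_rng(n_features, "dp-oracle")
        y = np.repeat([0, 1], 40)
        X = rng.normal(size=(80, n_features))
        X[:, 0] += 1.5 * y
        assert np.allclose(discriminant_power(X, y), oracle_dp(X, y),
                           atol=1e-8)

    def test_zero_variance_feature_scores_zero(self):
        rng = child_rng(2, "dp")
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 3))
        X[:, 1] += y
        X[:, 2] = 4.2
        dp = discriminant_power(X, y)
        assert dp[2] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            discriminant_power(np.zeros((10, 2)), np.zeros(10, dtype=int))


class TestStableSelect:
    def test_informative_feature_survives_folds(self):
        kept = 0
        for seed in range(10):
            rng = child_rng(seed, "sel")
            y = np.tile(np.repeat([0, 1], 10), 6)  # classes in every block
            X = rng.normal(size=(120, 20))
            X[:, 7] += 2.5 * y
            sel = stable_select(X, y, seed=seed)
            kept += bool(sel.stable_mask[7])
        assert kept >= 9

    def test_impossible_threshold_empties_mask(self):
        rng = child_rng(0, "sel")
        y = np.tile([0, 1], 30)
        X = rng.normal(size=(60, 5))
        sel = stable_select(X, y, threshold=100.0)
        assert not sel.stable_mask.any()

    def test_duplicated_data_reduces_to_single_fold(self):
        rng = child_rng(3, "sel")
        y1 = np.tile([0, 1], 20)
        X1 = rng.normal(size=(40, 8))
        X1[:, 2] += 2 * y1
        X = np.tile(X1, (3, 1))
        y = np.tile(y1, 3)
        sel = stable_select(X, y, n_folds=3)
        single = discriminant_power(X1, y1) > 1.0
        assert np.array_equal(sel.stable_mask, single)
        # identical folds: per-fold DP identical too
        assert np.allclose(sel.dp_per_fold[0], sel.dp_per_fold[2])

    def test_insufficient_class_members_rejected(self):
        with pytest.raises(ValueError):
            stable_select(np.zeros((5, 2)), np.array([0, 0, 0, 0, 1]))


def oracle_lda_posterior(X_train, y_train, X_test):
    """Closed-form two-class LDA posteriors: class means, pooled covariance
    (dof n-2), Gaussian class-conditionals, Bayes rule with empirical priors."""
    X0, X1 = X_train[y_train == 0], X_train[y_train == 1]
    m0, m1 = X0.mean(0), X1.mean(0)
    S = ((X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)) / (len(X_train) - 2)
    Si = np.linalg.inv(S)
    p1 = len(X1) / len(X_train)
    out = np.empty((len(X_test), 2))
    for i, x in enumerate(X_test):
        l0 = -0.5 * (x - m0) @ Si @ (x - m0) + np.log(1 - p1)
        l1 = -0.5 * (x - m1) @ Si @ (x - m1) + np.log(p1)
        m = max(l0, l1)
        e0, e1 = np.exp(l0 - m), np.exp(l1 - m)
        out[i] = [e0 / (e0 + e1), e1 / (e0 + e1)]
    return out


class TestGaussianClassifier:
    def test_single_prototype_pooled_equals_lda(self):
        rng = child_rng(0, "lda")
        y = np.repeat([0, 1], 60)
        X = rng.normal(size=(120, 3))
        X[y == 1] += [1.5, -0.5, 0.7]
        clf = GaussianClassifier(n_prototypes=1, covariance="pooled",
                                 reg=0.0).fit(X, y)
        post = clf.predict_posterior(X)
        assert np.allclose(post, oracle_lda_posterior(X, y, X), atol=1e-6)

    def test_prototypes_recover_bimodal_class_structure(self):
        hits = 0
        for seed in range(10):
            rng = child_rng(seed, "proto")
            centers = {0: [(-6, 0), (6, 0)], 1: [(0, -6), (0, 6)]}
            X, y = [], []
            for c, cs in centers.items():
                for mu in cs:
                    X.append(rng.normal(mu, 0.5, size=(40, 2)))
                    y += [c] * 40
            X = np.vstack(X)
            y = np.array(y)
            clf = GaussianClassifier(n_prototypes=2, seed=seed).fit(X, y)
            tol = 3 * 0.5 / np.sqrt(40)
            ok = all(
                np.linalg.norm(clf.means_[c] - np.asarray(mu), axis=1).min() < tol
                for c, cs in centers.items() for mu in cs
            )
            hits += ok
        assert hits >= 9

    def test_equidistant_point_splits_posterior(self):
        noise = child_rng(5, "eq").normal(0, 0.3, (10, 2))
        # mirror-symmetric classes: the origin is exactly equidistant
        X = np.vstack([noise - [1.0, 0.0], -noise + [1.0, 0.0]])
        y = np.repeat([0, 1], 10)
        clf = GaussianClassifier(n_prototypes=1, covariance="pooled").fit(X, y)
        post = clf.predict_posterior(np.array([[0.0, 0.0]]))
        assert np.allclose(post, [[0.5, 0.5]], atol=1e-9)

    def test_posteriors_normalize(self):
        rng = child_rng(1, "norm")
        X = rng.normal(size=(80, 4))
        y = np.repeat([0, 1], 40)
        X[y == 1, 0] += 1
        clf = GaussianClassifier(n_prototypes=2, seed=0).fit(X, y)
        post = clf.predict_posterior(rng.normal(size=(30, 4)))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(post >= 0)

    def test_infinite_covariance_limit_gives_priors(self):
        rng = child_rng(2, "lim")
        X = rng.normal(size=(60, 2))
        y = np.repeat([0, 1], 30)
        X[y == 1] += 2
        clf = GaussianClassifier(n_prototypes=1, seed=0).fit(X, y)
        for c in clf.variances_:
            clf.variances_[c] = np.full_like(clf.variances_[c], 1e12)
        post = clf.predict_posterior(rng.normal(size=(10, 2)))
        assert np.allclose(post, 0.5, atol=1e-3)

    def test_point_at_target_prototype_is_confident(self):
        rng = child_rng(3, "conf")
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(20, 1, (50, 2))])
        y = np.repeat([0, 1], 50)
        clf = GaussianClassifier(n_prototypes=1, seed=0).fit(X, y)
        score = clf.predict_target_score(np.array([[20.0, 20.0]]))
        assert score[0] > 0.99

    def test_too_many_prototypes_rejected(self):
        with pytest.raises(ValueError, match="prototypes"):
            GaussianClassifier(n_prototypes=4).fit(
                np.zeros((6, 2)), np.array([0, 0, 0, 1, 1, 1]))

    def test_json_round_trip(self, tmp_path):
        rng = child_rng(4, "json")
        X = rng.normal(size=(60, 3))
        y = np.repeat([0, 1], 30)
        X[y == 1] += 1
        clf = GaussianClassifier(n_prototypes=2, seed=0).fit(X, y)
        path = tmp_path / "model.json"
        clf.save(path)
        clone = GaussianClassifier.load(path)
        assert np.allclose(clone.predict_posterior(X),
                           clf.predict_posterior(X), atol=1e-12)


class TestHarden:
    def test_threshold_rule(self):
        out = harden(np.array([0.7, 0.3, 0.5]))
        assert out.tolist() == [1, 0, 0]  # exact threshold -> distractor

    def test_all_at_threshold(self):
        assert harden(np.full(5, 0.5)).sum() == 0


class TestLdaEnsemble:
    @staticmethod
    def windowed_data(rng, n_trials=200, n_channels=4, n_samples=20,
                      signal_window=None, fs=40.0):
        X = rng.normal(size=(n_trials, n_channels, n_samples))
        y = np.zeros(n_trials, dtype=int)
        y[rng.choice(n_trials, n_trials // 4, replace=False)] = 1
        if signal_window is not None:
            spw = int(round(0.100 * fs))
            sl = slice(signal_window * spw, (signal_window + 1) * spw)
            X[y == 1, :, sl] += 1.0
        return X, y

    def test_five_windows_for_default_epoch(self):
        """The 200-700 ms epoch at 32 Hz (16 samples) splits into exactly
        5 classifiers with 100-ms windows."""
        rng = child_rng(0, "ens")
        X = rng.normal(size=(60, 8, 16))
        y = np.repeat([0, 1], 30)
        ens = LdaEnsemble().fit(X, y, sample_rate=32.0)
        assert ens.n_windows_ == 5

    def test_informative_window_carries_discrimination(self):
        wins = 0
        for seed in range(10):
            rng = child_rng(seed, "ens2")
            X, y = self.windowed_data(rng, signal_window=2)
            full = LdaEnsemble().fit(X, y, 40.0)
            auc_full = roc_auc_score(y, full.decision_scores(X))
            X_wo = np.delete(X, np.s_[8:12], axis=2)  # drop window 2 samples
            rest = LdaEnsemble().fit(X_wo, y, 40.0)   # 16 samples -> 4 windows
            auc_rest = roc_auc_score(y, rest.decision_scores(X_wo))
            wins += auc_full > auc_rest
        assert wins >= 9

    def test_identical_windows_fuse_proportionally(self):
        rng = child_rng(1, "ens3")
        block = rng.normal(size=(100, 3, 4))
        y = np.repeat([0, 1], 50)
        block[y == 1] += 0.5
        X = np.tile(block, (1, 1, 4))  # 4 identical 100-ms windows
        ens = LdaEnsemble().fit(X, y, 40.0)
        fused = ens.decision_scores(X)
        single = LdaEnsemble().fit(block, y, 40.0).decision_scores(block)
        r = np.corrcoef(fused, single)[0, 1]
        assert r > 1 - 1e-9

    def test_overlong_window_rejected(self):
        rng = child_rng(2, "ens4")
        X, y = self.windowed_data(rng)
        with pytest.raises(ValueError):
            LdaEnsemble(window_ms=600.0).fit(X, y, 32.0)
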