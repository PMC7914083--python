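"""The improved ratio triplet loss, its analytic gradients versus finite
differences (the module's central oracle), PSD projection, and the
alternating optimizer."""

import numpy as np
import pytest
import scipy.linalg

from tripletmetric.config import LossConfig, TrainConfig
from tripletmetric.metric import (
    IdentityExtractor,
    MetricMatrix,
    improved_triplet_loss,
    loss_grad_features,
    loss_grad_metric,
    mahalanobis_distance,
    optimize_alternating,
    original_triplet_loss,
    psd_project,
)


def random_fixture(seed, n=6, d=4, n_triplets=3, mu=0.5, margin=1.0):
    """Random embeddings / PSD metric / triplets, rejecting fixtures whose
    hinge sits within 1e-2 of its kink (where the loss is not
    differentiable)."""
    rng = np.random.default_rng(seed)
    cfg = LossConfig(margin=margin, balance_mu=mu)
    while True:
        X = rng.normal(size=(n, d))
        T = [tuple(rng.choice(n, size=3, replace=False)) for _ in range(n_triplets)]
        A = rng.normal(size=(d, d))
        M = A @ A.T / d + 0.1 * np.eye(d)
        rep = improved_triplet_loss(X, T, M, cfg)
        if np.abs(rep.per_triplet_Dx).min() > 1e-2:
            return X, T, M, cfg


def fd_grad_features(X, T, M, cfg, h=1e-5):
    num = np.zeros_like(X)
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            Xp, Xm = X.copy(), X.copy()
            Xp[i, j] += h
            Xm[i, j] -= h
            num[i, j] = (
                improved_triplet_loss(Xp, T, M, cfg).total
                - improved_triplet_loss(Xm, T, M, cfg).total
            ) / (2 * h)
    return num


def fd_grad_metric(X, T, M, cfg, h=1e-6):
    num = np.zeros_like(M)
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            Mp, Mm = M.copy(), M.copy()
            Mp[i, j] += h
            Mm[i, j] -= h
            num[i, j] = (
                improved_triplet_loss(X, T, Mp, cfg).total
                - improved_triplet_loss(X, T, Mm, cfg).total
            ) / (2 * h)
    return num


class TestMahalanobisDistance:
    def test_identity_metric_is_squared_euclidean(self):
        f, g = np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 5.0])
        assert mahalanobis_distance(f, g, np.eye(3)) == pytest.approx(np.sum((f - g) ** 2))

    def test_coincident_points(self):
        f = np.array([0.3, -0.7])
        assert mahalanobis_distance(f, f, np.eye(2)) == 0.0

    def test_hand_worked_quadratic_form(self):
        M = np.array([[2.0, 1.0], [1.0, 2.0]])
        # diff = (1, -1): 1*2 + 1*(-1) + (-1)*1 + 1*2 = 2
        assert mahalanobis_distance([1, 0], [0, 1], M) == pytest.approx(2.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis_distance([1, 0], [0, 1, 2], np.eye(2))


class TestOriginalTripletLoss:
    def test_satisfied_triplet_contributes_zero(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0]])
        assert original_triplet_loss(X, [(0, 1, 2)], margin=0.5) == 0.0

    def test_degenerate_triplet_contributes_margin(self):
        X = np.zeros((1, 2))
        assert original_triplet_loss(X, [(0, 0, 0)], margin=0.7) == pytest.approx(0.7)

    def test_scalar_arithmetic_case(self):
        # d_plus = 1, d_minus = 2 (squared), margin 0.5 -> max(0, -0.5) = 0
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, np.sqrt(2.0)]])
        assert original_triplet_loss(X, [(0, 1, 2)], margin=0.5) == 0.0

    def test_bad_indices_rejected(self):
        with pytest.raises(ValueError):
            original_triplet_loss(np.zeros((2, 2)), [(0, 1, 5)], 1.0)


class TestImprovedTripletLoss:
    def test_hinge_boundary_inactive(self):
        # A = B + alpha exactly -> D_x = 0
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, np.sqrt(2.0)]])
        rep = improved_triplet_loss(X, [(0, 1, 2)], np.eye(2), LossConfig(1.0, 0.0))
        assert rep.per_triplet_Dx[0] == pytest.approx(0.0)
        assert rep.active_count == 0

    def test_anchor_equals_positive(self):
        # B = 0, A = 2 alpha -> D_x = -1 hinged to 0; pairwise term 0
        alpha = 0.8
        X = np.array([[0.0, 0.0], [0.0, 0.0], [np.sqrt(2 * alpha), 0.0]])
        rep = improved_triplet_loss(X, [(0, 1, 2)], np.eye(2), LossConfig(alpha, 3.0))
        assert rep.total == pytest.approx(0.0)

    def test_scalar_worked_example(self):
        cfg = LossConfig(margin=1.0, balance_mu=0.0)
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0]])
        rep = improved_triplet_loss(X, [(0, 1, 2)], np.eye(2), cfg)
        assert rep.per_triplet_Dx[0] == pytest.approx(1.0 - 9.0 / 2.0)
        assert rep.total == pytest.approx(0.0)
        X2 = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        rep2 = improved_triplet_loss(X2, [(0, 1, 2)], np.eye(2), cfg)
        assert rep2.total == pytest.approx(0.5)

    def test_empty_triplets_rejected(self):
        with pytest.raises(ValueError):
            improved_triplet_loss(np.zeros((2, 2)), [], np.eye(2), LossConfig())

    def test_zero_margin_zero_b_guarded(self):
        X = np.zeros((3, 2))
        with pytest.raises(ZeroDivisionError):
            improved_triplet_loss(X, [(0, 1, 2)], np.eye(2), LossConfig(0.0, 0.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegative_for_psd_metric(self, seed):
        X, T, M, cfg = random_fixture(seed)
        Mp = psd_project(M)
        assert improved_triplet_loss(X, T, Mp, cfg).total >= 0.0

    def test_identity_metric_ranks_like_euclidean_ratio(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 3))
        T = [tuple(rng.choice(10, 3, replace=False)) for _ in range(8)]
        cfg = LossConfig(margin=1.0, balance_mu=0.0)
        rep = improved_triplet_loss(X, T, np.eye(3), cfg)
        ratio = []
        for a, p, n in T:
            A = np.sum((X[a] - X[n]) ** 2)
            B = np.sum((X[a] - X[p]) ** 2)
            ratio.append(1.0 - A / (B + 1.0))
        assert np.array_equal(np.argsort(rep.per_triplet_Dx), np.argsort(ratio))


class TestGradientOracles:
    @pytest.mark.parametrize("seed", range(20))
    def test_feature_gradients_match_finite_differences(self, seed):
        X, T, M, cfg = random_fixture(seed)
        ana = loss_grad_features(X, T, M, cfg).grad_features
        num = fd_grad_features(X, T, M, cfg)
        scale = max(np.abs(num).max(), 1e-12)
        assert np.abs(ana - num).max() / scale < 1e-4

    @pytest.mark.parametrize("seed", range(20))
    def test_metric_gradients_match_finite_differences(self, seed):
        X, T, M, cfg = random_fixture(seed)
        ana = loss_grad_metric(X, T, M, cfg).grad_metric
        num = fd_grad_metric(X, T, M, cfg)
        scale = max(np.abs(num).max(), 1e-12)
        assert np.abs(ana - num).max() / scale < 1e-4

    def test_all_inactive_and_zero_mu_gives_zero_gradient(self):
        # negatives far away -> every D_x < 0; with mu = 0 nothing fires
        X = np.array([[0.0, 0.0], [0.1, 0.0], [50.0, 0.0]])
        cfg = LossConfig(margin=1.0, balance_mu=0.0)
        g = loss_grad_features(X, [(0, 1, 2)], np.eye(2), cfg)
        gm = loss_grad_metric(X, [(0, 1, 2)], np.eye(2), cfg)
        assert np.allclose(g.grad_features, 0.0)
        assert np.allclose(gm.grad_metric, 0.0)

    def test_coincident_pair_has_zero_pairwise_gradient(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 0.0]])
        cfg = LossConfig(margin=1.0, balance_mu=2.0)
        g = loss_grad_features(X, [(0, 1, 2)], np.eye(2), cfg).grad_features
        assert np.allclose(g[1], 0.0)

    def test_inactive_triplet_metric_gradient_is_pairwise_outer_product(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [50.0, 0.0]])
        cfg = LossConfig(margin=1.0, balance_mu=1.0)
        gm = loss_grad_metric(X, [(0, 1, 2)], np.eye(2), cfg).grad_metric
        diff = X[0] - X[1]
        assert np.allclose(gm, np.outer(diff, diff))

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_gradient_is_symmetric(self, seed):
        X, T, M, cfg = random_fixture(seed)
        gm = loss_grad_metric(X, T, M, cfg).grad_metric
        assert np.allclose(gm, gm.T)


class TestPsdProjection:
    def test_fixed_point_on_psd_input(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(5, 5))
        P = A @ A.T
        assert np.abs(psd_project(P).M - P).max() < 1e-10

    def test_diagonal_truncation(self):
        out = psd_project(np.diag([3.0, -2.0])).M
        assert np.allclose(out, np.diag([3.0, 0.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_eigensolver(self, seed):
        rng = np.random.default_rng(seed)
        S = rng.normal(size=(5, 5))
        S = 0.5 * (S + S.T)
        # independent route: scipy's symmetric eigensolver
        vals, vecs = scipy.linalg.eigh(S)
        expect = (vecs * np.maximum(vals, 0.0)) @ vecs.T
        assert np.abs(psd_project(S).M - expect).max() < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_and_psd(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 6))
        once = psd_project(X)
        twice = psd_project(once)
        assert np.abs(twice.M - once.M).max() < 1e-10
        assert once.min_eigenvalue() >= -1e-8
        assert np.allclose(once.M, once.M.T)

    def test_nonfinite_rejected(self):
        bad = np.eye(3)
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            psd_project(bad)


class TestAlternatingOptimizer:
    def _features(self, seed=0, n=30, d=4):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [
                rng.normal(scale=0.3, size=(n, d)) + np.array([1.0, 0, 0, 0]),
                rng.normal(scale=0.3, size=(n, d)) - np.array([1.0, 0, 0, 0]),
            ]
        )
        y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
        return X, y

    def test_zero_learning_rates_leave_metric_unchanged(self):
        X, y = self._features()
        cfg = TrainConfig(seed=0, outer_iters=3, lr_w=0.0, lr_M=0.0)
        _, M, hist = optimize_alternating(X, y, IdentityExtractor(), cfg)
        assert np.array_equal(M.M, np.eye(4))
        assert len(hist) == 3

    def test_metric_stays_psd_through_training(self):
        X, y = self._features(1)
        cfg = TrainConfig(seed=1, outer_iters=10, lr_M=0.1)
        _, M, _ = optimize_alternating(X, y, IdentityExtractor(), cfg)
        assert M.min_eigenvalue() >= -1e-8

    def test_separable_features_learn_discriminative_metric(self):
        # 50 iterations on linearly separable features: loss falls and the
        # learned metric pulls classes apart more than within-class spread
        X, y = self._features(2)
        cfg = TrainConfig(
            seed=2, outer_iters=50, inner_batches=1, metric_steps=3, lr_M=0.05,
            margin=1.0, batch_L=8,
        )
        _, M, hist = optimize_alternating(X, y, IdentityExtractor(), cfg)
        assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]
        Ms = M.M
        within, between = [], []
        for i in range(len(X)):
            for j in range(i + 1, len(X)):
                d = float((X[i] - X[j]) @ Ms @ (X[i] - X[j]))
                (within if y[i] == y[j] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_single_class_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError):
            optimize_alternating(X, np.zeros(5, int), IdentityExtractor(), TrainConfig())
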