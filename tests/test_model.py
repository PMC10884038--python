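"""Unit and property tests of the optimization core.

Derivatives are checked against central finite differences of the objective,
closed-form step sizes against dense 1-D grid scans, and the fit against its
monotone-descent and determinism contracts.
"""

import numpy as np
import pytest

from sccase import (
    ModelParams,
    enhance,
    fit,
    gradients,
    jaccard_similarity,
    loss,
    nmf_init,
    optimal_step_w,
    optimal_step_z,
    sample_mask,
    tfidf_transform,
    update_h,
)
from sccase.model import DegenerateDirectionError, _column_normalize

from conftest import make_pbc


def finite_difference(f, A, h=1e-6):
    """Central-difference gradient of a scalar function of one matrix."""
    G = np.zeros_like(A)
    flat = G.ravel()
    for i in range(A.size):
        up, down = A.copy().ravel(), A.copy().ravel()
        up[i] += h
        down[i] -= h
        flat[i] = (f(up.reshape(A.shape)) - f(down.reshape(A.shape))) / (2 * h)
    return G


class TestJaccard:
    def test_identical_profiles_similarity_one(self):
        B = np.tile([[1], [0], [1]], (1, 3))
        Z = jaccard_similarity(B)
        np.testing.assert_allclose(Z, 1.0)

    def test_disjoint_supports_zero(self):
        B = np.array([[1, 0], [0, 1]])
        assert jaccard_similarity(B)[0, 1] == 0.0

    def test_brute_force_set_arithmetic(self):
        # supports {0,1} vs {0,2}: |∩|=1, |∪|=3
        B = np.array([[1, 1], [1, 0], [0, 1]])
        Z = jaccard_similarity(B)
        assert Z[0, 1] == pytest.approx(1 / 3)
        np.testing.assert_allclose(Z, Z.T)
        np.testing.assert_allclose(np.diag(Z), 1.0)

    def test_empty_support_raises(self):
        with pytest.raises(ValueError, match="empty support"):
            jaccard_similarity(np.array([[1, 0], [1, 0]]))


class TestNMFInit:
    def test_block_structured_matrix_recovered(self, rng):
        # disjoint blocks factor exactly at the true rank
        W_true = np.zeros((12, 3))
        for c in range(3):
            W_true[4 * c : 4 * (c + 1), c] = rng.random(4) + 0.5
        H_true = np.zeros((3, 9))
        for c in range(3):
            H_true[c, 3 * c : 3 * (c + 1)] = rng.random(3) + 0.5
        X = W_true @ H_true
        W, H = nmf_init(X, 3, seed=0, max_iter=2000)
        assert np.linalg.norm(X - W @ H) <= 1e-6 * np.linalg.norm(X)

    def test_rank_one_constant_matrix(self):
        X = np.full((4, 5), 2.0)
        W, H = nmf_init(X, 1, seed=0, max_iter=1000)
        np.testing.assert_allclose(W @ H, X, rtol=1e-5)

    def test_deterministic(self, rng):
        X = rng.random((8, 6))
        W1, H1 = nmf_init(X, 2, seed=5)
        W2, H2 = nmf_init(X, 2, seed=5)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(H1, H2)

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            nmf_init(rng.random((4, 6)), 5)


def test_eigengap_heuristic_finds_planted_block_count(rng):
    from sccase import estimate_k_eigengap

    B = np.zeros((30, 24))
    for c in range(3):
        B[10 * c : 10 * (c + 1), 8 * c : 8 * (c + 1)] = rng.random((10, 8)) < 0.9
    B[0, B.sum(axis=0) == 0] = 1
    with pytest.warns(UserWarning, match="heuristic"):
        k = estimate_k_eigengap(B)
    assert k == 3


class TestMask:
    def test_degenerate_bernoulli_all_ones(self):
        np.testing.assert_array_equal(sample_mask(4, 1.0, 0), np.ones((4, 4)))

    def test_law_of_large_numbers(self):
        fractions = [sample_mask(1000, 0.8, s).mean() for s in range(10)]
        assert abs(np.mean(fractions) - 0.8) < 0.01

    def test_deterministic(self):
        np.testing.assert_array_equal(sample_mask(50, 0.5, 9), sample_mask(50, 0.5, 9))

    def test_zero_probability_rejected(self):
        with pytest.raises(ValueError, match="annihilate"):
            sample_mask(5, 0.0, 0)


class TestLoss:
    def test_vanishing_terms(self, small_instance):
        X, W, H, Z, R, _ = small_instance
        p = ModelParams(k=2, lam=0.0, gamma1=0.0, gamma2=0.0)
        f = loss(X, np.zeros_like(W), np.zeros_like(H), Z, R, p)
        assert f == pytest.approx(np.linalg.norm(X @ (Z * R)) ** 2)

    def test_exact_fit_zero_loss(self, rng):
        # construct X with X·(HᵀH) = WH and Z = HᵀH so both residuals vanish
        W = rng.random((6, 2))
        H = rng.random((2, 5))
        Z = H.T @ H
        X = W @ np.linalg.pinv(H.T)  # pinv(Hᵀ)Hᵀ = I for full-row-rank H
        R = np.ones((5, 5))
        p = ModelParams(k=2, lam=3.0, gamma1=0.0, gamma2=0.0)
        assert loss(X, W, H, Z, R, p) == pytest.approx(0.0, abs=1e-18)

    def test_norm_equals_trace_form(self, small_instance):
        X, W, H, Z, R, p = small_instance
        f_norm = loss(X, W, H, Z, R, p, form="norm")
        f_trace = loss(X, W, H, Z, R, p, form="trace")
        assert abs(f_norm - f_trace) <= 1e-8 * max(abs(f_norm), 1.0)


class TestGradients:
    def test_matches_finite_differences(self, small_instance):
        X, W, H, Z, R, p = small_instance
        D1, D3, D2 = gradients(X, W, H, Z, R, p)
        fd_W = finite_difference(lambda A: loss(X, A, H, Z, R, p), W)
        fd_H = finite_difference(lambda A: loss(X, W, A, Z, R, p), H)
        fd_Z = finite_difference(lambda A: loss(X, W, H, A, R, p), Z)
        assert np.abs(D1 - fd_W).max() <= 1e-4
        assert np.abs(D3 - fd_H).max() <= 1e-4
        assert np.abs(D2 - fd_Z).max() <= 1e-4

    def test_w_gradient_vanishes_at_ridge_solution(self, small_instance):
        X, _, H, Z, R, p = small_instance
        W_star = (
            X @ (Z * R) @ H.T @ np.linalg.inv(H @ H.T + p.gamma1 * np.eye(p.k))
        )
        D1, _, _ = gradients(X, W_star, H, Z, R, p)
        assert np.abs(D1).max() < 1e-10

    def test_w_zero_gives_data_term_only(self, small_instance):
        X, W, H, Z, R, p = small_instance
        D1, _, _ = gradients(X, np.zeros_like(W), H, Z, R, p)
        np.testing.assert_allclose(D1, -2 * X @ (Z * R) @ H.T)


class TestStepSizes:
    def test_w_step_is_grid_scan_minimizer(self, small_instance):
        X, W, H, Z, R, p = small_instance
        D1, _, _ = gradients(X, W, H, Z, R, p)
        d1 = optimal_step_w(X, W, H, Z, R, D1, p)
        grid = np.linspace(0, 2 * d1, 10001)
        vals = [loss(X, W - d * D1, H, Z, R, p) for d in grid]
        assert abs(grid[int(np.argmin(vals))] - d1) <= grid[1] - grid[0]

    def test_w_step_reduces_to_printed_formula_without_ridge(self, small_instance):
        # with gamma1 = 0 the exact step equals the pure trace-ratio form
        X, W, H, Z, R, _ = small_instance
        p0 = ModelParams(k=2, lam=2.0, gamma1=0.0, gamma2=0.3)
        D1, _, _ = gradients(X, W, H, Z, R, p0)
        ZR = Z * R
        num = (
            -np.trace(H.T @ D1.T @ X @ ZR)
            - np.trace(ZR.T @ X.T @ D1 @ H)
            + np.trace(H.T @ W.T @ D1 @ H)
            + np.trace(H.T @ D1.T @ W @ H)
        )
        den = 2 * np.trace(H.T @ D1.T @ D1 @ H)
        assert optimal_step_w(X, W, H, Z, R, D1, p0) == pytest.approx(num / den)

    def test_w_descent_property(self, small_instance):
        X, W, H, Z, R, p = small_instance
        D1, _, _ = gradients(X, W, H, Z, R, p)
        d1 = optimal_step_w(X, W, H, Z, R, D1, p)
        assert loss(X, W - d1 * D1, H, Z, R, p) < loss(X, W, H, Z, R, p)

    def test_w_step_is_parabola_vertex(self, small_instance):
        X, W, H, Z, R, p = small_instance
        D1, _, _ = gradients(X, W, H, Z, R, p)
        f = lambda d: loss(X, W - d * D1, H, Z, R, p)
        # 3-point quadratic fit: vertex -b/2a
        d0, d1_, d2_ = 0.0, 0.1, 0.2
        a, b, _ = np.polyfit([d0, d1_, d2_], [f(d0), f(d1_), f(d2_)], 2)
        assert optimal_step_w(X, W, H, Z, R, D1, p) == pytest.approx(-b / (2 * a))

    def test_z_step_is_grid_scan_minimizer(self, small_instance):
        X, W, H, Z, R, p = small_instance
        _, _, D2 = gradients(X, W, H, Z, R, p)
        d2 = optimal_step_z(X, W, H, Z, R, D2, p)
        grid = np.linspace(0, 2 * d2, 10001)
        vals = [loss(X, W, H, Z - d * D2, R, p) for d in grid]
        assert abs(grid[int(np.argmin(vals))] - d2) <= grid[1] - grid[0]

    def test_z_step_lambda_zero_matches_data_term_minimizer(self, small_instance):
        X, W, H, Z, R, _ = small_instance
        p0 = ModelParams(k=2, lam=1e-300, gamma1=0.7, gamma2=0.3)
        p0.lam = 0.0  # pure data term
        _, _, D2 = gradients(X, W, H, Z, R, p0)
        d2 = optimal_step_z(X, W, H, Z, R, D2, p0)
        # independent closed form of the first term only:
        # argmin_d ||X((Z - d D2)∘R) - WH||²
        B = X @ (D2 * R)
        expected = np.vdot(B, X @ (Z * R) - W @ H) / np.vdot(B, B)
        assert d2 == pytest.approx(expected)

    def test_z_ascent_direction_gives_negative_step(self, small_instance):
        X, W, H, Z, R, p = small_instance
        _, _, D2 = gradients(X, W, H, Z, R, p)
        d2 = optimal_step_z(X, W, H, Z, R, -D2, p)  # constructed ascent direction
        assert d2 < 0

    def test_degenerate_direction_raises(self, small_instance):
        X, W, H, Z, R, p = small_instance
        with pytest.raises(DegenerateDirectionError):
            optimal_step_w(X, W, H, Z, R, np.zeros_like(W), p)


class TestUpdateH:
    def test_zero_gradient_is_noop(self, small_instance):
        X, W, H, Z, R, p = small_instance
        np.testing.assert_array_equal(update_h(X, W, H, Z, R, np.zeros_like(H), p), H)

    def test_backtracking_never_increases_loss(self, small_instance):
        X, W, H, Z, R, p = small_instance
        _, D3, _ = gradients(X, W, H, Z, R, p)
        H_new = update_h(X, W, H, Z, R, D3, p)
        assert loss(X, W, H_new, Z, R, p) <= loss(X, W, H, Z, R, p)

    def test_projection_clips_to_zero(self, small_instance):
        X, W, H, Z, R, p = small_instance
        D3 = np.full_like(H, 1e6)  # drives everything far negative
        H_new = update_h(X, W, H, Z, R, D3, p)
        assert H_new.min() >= 0.0


class TestFit:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_descent_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            m, n = rng.integers(6, 14), rng.integers(5, 12)
            X = rng.random((m, n))
            p = ModelParams(k=2, lam=float(rng.uniform(0.1, 100)), max_iter=15, seed=seed)
            trace = fit(X, p).loss_trace
            assert np.all(np.diff(trace) <= 0.0)

    def test_block_structure_concentrates_similarity(self, rng):
        # 3 planted blocks: final Z should weight within-block pairs more
        blocks = []
        for c in range(3):
            B = np.full((10, 6), 0.02)
            B[3 * c : 3 * c + 4, :] = 0.9
            blocks.append(B)
        X = (rng.random((10, 18)) < np.hstack(blocks)).astype(float)
        X[:, X.sum(axis=0) == 0] = 1
        Xt = tfidf_transform(make_pbc(X, "filtered"))
        res = fit(Xt, ModelParams(k=3, max_iter=60, seed=0))
        membership = np.repeat([0, 1, 2], 6)
        same = membership[:, None] == membership[None, :]
        off_diag = ~np.eye(18, dtype=bool)
        within = res.Z[same & off_diag].mean()
        between = res.Z[~same].mean()
        assert within > between

    def test_infinite_tolerance_stops_after_one_iteration(self, rng):
        X = rng.random((8, 6))
        res = fit(X, ModelParams(k=2, tol=np.inf, max_iter=50))
        assert res.n_iter == 1 and res.converged

    def test_deterministic_given_seed(self, rng):
        X = rng.random((10, 8))
        p = ModelParams(k=3, max_iter=10, seed=4)
        r1, r2 = fit(X, p), fit(X, p)
        np.testing.assert_array_equal(r1.Z, r2.Z)
        np.testing.assert_array_equal(r1.loss_trace, r2.loss_trace)

    def test_output_contracts(self, rng):
        X = rng.random((10, 8))
        res = fit(X, ModelParams(k=2, max_iter=10, seed=0))
        np.testing.assert_allclose(res.Z.sum(axis=0), 1.0, atol=1e-10)
        assert res.Z.min() >= 0 and res.W.min() >= 0 and res.H.min() >= 0
        assert len(res.loss_trace) == res.n_iter + 1

    def test_rejects_wrong_layer(self):
        X = make_pbc(np.ones((3, 3)), layer_tag="raw")
        with pytest.raises(ValueError, match="TF-IDF"):
            fit(X, ModelParams(k=2))


class TestEnhance:
    def test_identity_similarity(self, rng):
        X = rng.random((5, 4))
        np.testing.assert_array_equal(enhance(X, np.eye(4)), X)

    def test_uniform_column_averages(self, rng):
        X = rng.random((5, 4))
        Z = np.full((4, 4), 0.25)
        out = enhance(X, Z)
        np.testing.assert_allclose(out[:, 0], X.mean(axis=1))

    def test_hand_multiplied_3x3(self):
        X = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0], [3.0, 0.0, 0.0]])
        Z = np.array([[0.5, 0.0, 0.5], [0.5, 1.0, 0.0], [0.0, 0.0, 0.5]])
        expected = np.array([[0.5, 0.0, 1.5], [0.5, 1.0, 0.5], [1.5, 0.0, 1.5]])
        np.testing.assert_allclose(enhance(X, Z), expected)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="disagree"):
            enhance(rng.random((5, 4)), np.eye(3))


def test_column_normalize_handles_zero_columns():
    Z = np.zeros((3, 3))
    Z[0, 0] = 1.0
    out = _column_normalize(Z)
    np.testing.assert_allclose(out.sum(axis=0), 1.0)
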