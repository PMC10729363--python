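import numpy as np
import pytest

from mnclcda.predictor import (
    alternate_solve,
    embedding_kernel,
    laprls_loss,
    normalized_laplacian,
    score_matrix,
    solve_wc,
    solve_wd,
)


def random_instance(nc, nd, seed):
    rng = np.random.default_rng(seed)
    Ec = rng.normal(size=(nc, 3))
    Ed = rng.normal(size=(nd, 3))
    Kc = embedding_kernel(Ec, 0.5)
    Kd = embedding_kernel(Ed, 0.5)
    Lc = normalized_laplacian(Kc)
    Ld = normalized_laplacian(Kd)
    Y = (rng.random((nc, nd)) < 0.4).astype(float)
    return Kc, Kd, Lc, Ld, Y


def test_embedding_kernel_examples():
    K = embedding_kernel(np.ones((3, 2)), 2.0**-5)
    np.testing.assert_allclose(K, 1.0)
    K = embedding_kernel(np.array([[0.0], [1.0]]), 2.0**-5)
    assert K[0, 1] == pytest.approx(np.exp(-1.0 / 32.0))
    K = embedding_kernel(np.random.default_rng(0).normal(size=(4, 2)), 1e-12)
    np.testing.assert_allclose(K, 1.0, atol=1e-9)


def test_embedding_kernel_rejects_bad_inputs():
    with pytest.raises(ValueError):
        embedding_kernel(np.ones((2, 2)), 0.0)
    with pytest.raises(ValueError):
        embedding_kernel(np.array([[np.inf, 0.0]]), 0.5)


def test_normalized_laplacian_examples():
    L = normalized_laplacian(np.ones((2, 2)))
    np.testing.assert_allclose(L, [[0.5, -0.5], [-0.5, 0.5]])
    np.testing.assert_allclose(normalized_laplacian(np.eye(3)), np.zeros((3, 3)), atol=1e-12)


def test_normalized_laplacian_spectrum_on_random_kernels():
    rng = np.random.default_rng(6)
    for seed in range(5):
        E = rng.normal(size=(8, 3))
        L = normalized_laplacian(embedding_kernel(E, 0.7))
        np.testing.assert_allclose(L, L.T, atol=1e-12)
        eig = np.linalg.eigvalsh(L)
        assert eig.min() >= -1e-8 and eig.max() <= 2.0 + 1e-8


def test_laprls_loss_reference_values():
    Kc, Kd, Lc, Ld, Y = random_instance(4, 3, 0)
    # zero coefficients: loss is the constant term 4 ||Y||_F^2
    zero = laprls_loss(Kc, Kd, np.zeros((4, 3)), np.zeros((3, 4)), Lc, Ld, Y, 0.0, 0.0)
    assert zero == pytest.approx(4.0 * (Y**2).sum())


def test_loss_gradient_matches_analytic_form():
    """Central finite differences of the objective match the stated derivative."""
    Kc, Kd, Lc, Ld, Y = random_instance(4, 3, 1)
    rng = np.random.default_rng(2)
    Wc = rng.normal(size=(4, 3))
    Wd = rng.normal(size=(3, 4))
    analytic = 2.0 * Kc @ (Kc @ Wc + (Kd @ Wd).T - 2.0 * Y) + 2.0 * 0.5 * Lc @ Wc
    h = 1e-6
    numeric = np.zeros_like(Wc)
    for i in range(4):
        for j in range(3):
            Wp, Wm = Wc.copy(), Wc.copy()
            Wp[i, j] += h
            Wm[i, j] -= h
            numeric[i, j] = (
                laprls_loss(Kc, Kd, Wp, Wd, Lc, Ld, Y, 0.5, 0.125)
                - laprls_loss(Kc, Kd, Wm, Wd, Lc, Ld, Y, 0.5, 0.125)
            ) / (2 * h)
    np.testing.assert_allclose(analytic, numeric, atol=1e-5)


def test_solve_scalar_case():
    Wc = solve_wc(
        np.array([[2.0]]), np.array([[0.5]]), np.array([[1.0]]),
        np.array([[1.0]]), np.array([[1.0]]), 1.0,
    )
    assert Wc[0, 0] == pytest.approx(4.0 / 9.0)


def test_solve_interpolates_at_zero_penalty():
    Kc, Kd, Lc, Ld, Y = random_instance(5, 4, 3)
    Wd = np.zeros((4, 5))
    Wc = solve_wc(Kc, Lc, Kd, Wd, Y, 0.0)
    np.testing.assert_allclose(Kc @ Wc + (Kd @ Wd).T, 2.0 * Y, atol=1e-8)


@pytest.mark.parametrize("seed", range(3))
def test_solves_zero_the_gradient(seed):
    Kc, Kd, Lc, Ld, Y = random_instance(5, 4, seed)
    rng = np.random.default_rng(seed + 10)
    Wd = rng.normal(size=(4, 5))
    Wc = solve_wc(Kc, Lc, Kd, Wd, Y, 0.5)
    grad_c = 2.0 * Kc @ (Kc @ Wc + (Kd @ Wd).T - 2.0 * Y) + 2.0 * 0.5 * Lc @ Wc
    assert np.abs(grad_c).max() < 1e-6
    Wd2 = solve_wd(Kd, Ld, Kc, Wc, Y, 0.125)
    grad_d = 2.0 * Kd @ (Kd @ Wd2 + (Kc @ Wc).T - 2.0 * Y.T) + 2.0 * 0.125 * Ld @ Wd2
    assert np.abs(grad_d).max() < 1e-6


def test_alternate_solve_monotone_and_fixed_point():
    Kc, Kd, Lc, Ld, Y = random_instance(5, 4, 4)
    losses = []
    Wc = np.zeros((5, 4))
    Wd = np.zeros((4, 5))
    for sweep in range(5000):
        Wc = solve_wc(Kc, Lc, Kd, Wd, Y, 0.5, 1e-9)
        Wd = solve_wd(Kd, Ld, Kc, Wc, Y, 0.125, 1e-9)
        losses.append(laprls_loss(Kc, Kd, Wc, Wd, Lc, Ld, Y, 0.5, 0.125))
    assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))
    Wc2 = solve_wc(Kc, Lc, Kd, Wd, Y, 0.5, 1e-9)
    Wd2 = solve_wd(Kd, Ld, Kc, Wc2, Y, 0.125, 1e-9)
    assert np.abs(Wc2 - Wc).max() < 1e-8 and np.abs(Wd2 - Wd).max() < 1e-8


def test_alternate_solve_matches_gradient_descent_oracle():
    """Gradient descent (exact line search) reaches the same loss level."""
    Kc, Kd, Lc, Ld, Y = random_instance(5, 4, 5)
    Wc, Wd = alternate_solve(Kc, Kd, Lc, Ld, Y, 0.5, 0.125, sweeps=2000, jitter=1e-10)
    best = laprls_loss(Kc, Kd, Wc, Wd, Lc, Ld, Y, 0.5, 0.125)
    lam_c, lam_d = 0.5, 0.125
    Gc = np.zeros((5, 4))
    Gd = np.zeros((4, 5))
    for _ in range(5000):
        R = Kc @ Gc + (Kd @ Gd).T - 2.0 * Y
        gc = 2.0 * Kc @ R + 2.0 * lam_c * Lc @ Gc
        gd = 2.0 * Kd @ R.T + 2.0 * lam_d * Ld @ Gd
        # exact line search along the negative gradient of the quadratic
        R_lin = Kc @ gc + (Kd @ gd).T
        a = (R_lin**2).sum() + lam_c * np.trace(gc.T @ Lc @ gc) + lam_d * np.trace(gd.T @ Ld @ gd)
        b = (gc**2).sum() + (gd**2).sum()
        if a <= 0 or b == 0:
            break
        t = b / (2.0 * a)
        Gc -= t * gc
        Gd -= t * gd
    gd_loss = laprls_loss(Kc, Kd, Gc, Gd, Lc, Ld, Y, 0.5, 0.125)
    assert abs(gd_loss - best) < 1e-4


def test_convexity_along_random_segments():
    Kc, Kd, Lc, Ld, Y = random_instance(5, 4, 6)
    rng = np.random.default_rng(7)
    for _ in range(10):
        Wc0, Wc1 = rng.normal(size=(2, 5, 4))
        Wd0, Wd1 = rng.normal(size=(2, 4, 5))
        ts = np.linspace(0, 1, 9)
        vals = [
            laprls_loss(
                Kc, Kd, (1 - t) * Wc0 + t * Wc1, (1 - t) * Wd0 + t * Wd1,
                Lc, Ld, Y, 0.5, 0.125,
            )
            for t in ts
        ]
        second = np.diff(vals, 2)
        assert (second >= -1e-8).all()


def test_lambda_shrinks_penalty_monotonically():
    Kc, Kd, Lc, Ld, Y = random_instance(6, 5, 8)
    penalties = []
    for lam in [0.0, 0.25, 1.0, 4.0, 16.0]:
        Wc, Wd = alternate_solve(Kc, Kd, Lc, Ld, Y, lam, lam, sweeps=10, jitter=1e-9)
        penalties.append(np.trace(Wc.T @ Lc @ Wc) + np.trace(Wd.T @ Ld @ Wd))
    assert all(b <= a + 1e-8 for a, b in zip(penalties, penalties[1:]))


def test_score_matrix_composition():
    Kc, Kd, Lc, Ld, Y = random_instance(4, 3, 9)
    rng = np.random.default_rng(10)
    Wc = rng.normal(size=(4, 3))
    Wd = rng.normal(size=(3, 4))
    np.testing.assert_allclose(
        score_matrix(Kc, Wc, Kd, Wd), (Kc @ Wc + (Kd @ Wd).T) / 2.0, atol=1e-12
    )
    np.testing.assert_array_equal(score_matrix(Kc, np.zeros((4, 3)), Kd, np.zeros((3, 4))), 0.0)
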