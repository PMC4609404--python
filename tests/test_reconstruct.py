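import math
import warnings

import numpy as np
import pytest

import dictsir as ds
from dictsir.reconstruct import (ReconConfig, awr_step, compute_c_d,
                                 compute_p_q, gpbb_reconstruct,
                                 run_reconstruction, sart_reconstruct,
                                 sir_dl_step, weighted_delta, _tv_value_grad)
from dictsir.sparse_model import (PatchDictionary, PatchScheme,
                                  extract_patches, omp_batch,
                                  patch_adjoint_accumulate)


@pytest.fixture(scope="module")
def toy():
    """Overdetermined noiseless toy scan of a smooth 8x8 image."""
    geom = ds.build_geometry(20, 18.0, 12, 8, 2.0)
    A = ds.build_system_matrix(geom)
    rng = np.random.default_rng(12)
    yy, xx = np.mgrid[0:8, 0:8]
    mu = 0.05 + 0.03 * np.exp(-((xx - 3.5) ** 2 + (yy - 3.5) ** 2) / 8.0)
    sino = ds.simulate_scan(mu, geom, 0.0, A=A)
    return geom, A, mu, sino


class TestSart:
    def test_converges_to_consistent_solution(self, toy):
        geom, A, mu, sino = toy
        cfg = ReconConfig(sart_sweeps=2000, stop_tol=1e-9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sart_reconstruct(sino, A, cfg)
        # overdetermined consistent system: the only solution is mu itself
        assert np.abs(res.image - mu).max() < 1e-4

    def test_truth_is_a_fixed_point(self, toy):
        geom, A, mu, sino = toy
        cfg = ReconConfig(sart_sweeps=1, stop_tol=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sart_reconstruct(sino, A, cfg, init_image=mu)
        assert np.abs(res.image - mu).max() <= 1e-10

    def test_output_nonnegative(self, toy):
        geom, A, mu, sino = toy
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sart_reconstruct(sino, A, ReconConfig(sart_sweeps=5))
        assert np.all(res.image >= 0)

    def test_rejects_mismatched_sinogram(self, toy, toy_system32):
        geom, A, mu, sino = toy
        with pytest.raises(ValueError):
            sart_reconstruct(sino, toy_system32)


class TestGpbb:
    def test_zero_tv_recovers_weighted_least_squares(self, toy):
        geom, A, mu, sino = toy
        cfg = ReconConfig(tv_weight=0.0, gpbb_iters=3000, stop_tol=1e-12,
                          init="zeros")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gpbb_reconstruct(sino, A, cfg)
        assert np.abs(res.image - mu).max() < 1e-4

    def test_tv_lower_than_sart_on_piecewise_constant_phantom(self):
        n = 32
        mu = np.zeros((n, n))
        mu[8:24, 8:24] = 0.08
        mu[12:20, 12:20] = 0.04
        geom = ds.build_geometry(12, 30.0, 64, n, 2.0)  # sparse views
        A = ds.build_system_matrix(geom)
        sino = ds.simulate_scan(mu, geom, 0.0, A=A)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sart = sart_reconstruct(sino, A, ReconConfig(sart_sweeps=150))
            gpbb = gpbb_reconstruct(sino, A, ReconConfig(gpbb_iters=300))
        tv = lambda img: _tv_value_grad(img, 1e-8)[0]
        assert tv(gpbb.image) < tv(sart.image)


class TestSurrogateCoefficients:
    def test_p_matches_dense_oracle(self, small_system, rng):
        omega = rng.random(small_system.shape[0]) + 0.5
        scheme = PatchScheme(4, 2, 8)
        p, q = compute_p_q(small_system, omega, scheme)
        dense = small_system.matrix.toarray()
        p_oracle = dense.T @ (omega * dense.sum(axis=1))
        assert np.allclose(p, p_oracle, rtol=1e-12)

    def test_p_linear_in_omega(self, small_system, rng):
        omega = rng.random(small_system.shape[0])
        scheme = PatchScheme(4, 2, 8)
        p1, _ = compute_p_q(small_system, omega, scheme)
        p2, _ = compute_p_q(small_system, 2.0 * omega, scheme)
        assert np.allclose(p2, 2.0 * p1)

    def test_q_is_coverage_count(self, small_system):
        scheme = PatchScheme(4, 1, 8)
        _, q = compute_p_q(small_system, np.ones(small_system.shape[0]),
                           scheme)
        assert q.reshape(8, 8)[4, 4] == 16  # interior: 4x4 patches cover it

    def test_rj_qj_identity(self, small_system, rng):
        """The reweighting factors satisfy r_j q_j = p_j / 2 exactly."""
        omega = rng.random(small_system.shape[0]) + 0.1
        scheme = PatchScheme(4, 2, 8)
        p, q = compute_p_q(small_system, omega, scheme)
        ok = (p > 0) & (q > 0)
        r = p[ok] / (2.0 * q[ok])
        assert np.allclose(r * q[ok], p[ok] / 2.0, rtol=1e-15)


def _exact_patch_dictionary():
    """2x2 patch dictionary containing the 4 unit vectors (plus noise
    atoms) so every patch is exactly representable at L=4."""
    rng = np.random.default_rng(5)
    atoms = np.concatenate([np.eye(4), rng.standard_normal((4, 4))], axis=1)
    return PatchDictionary(atoms, 2)


class TestTargets:
    def test_consistent_image_gives_c_equal_mu(self, toy):
        geom, A, mu, sino = toy
        scheme = PatchScheme(2, 1, 8)
        D = _exact_patch_dictionary()
        X = extract_patches(mu, scheme)
        means = X.mean(axis=0)
        alpha = omp_batch(D, X - means[None, :], L=4)
        p, q = compute_p_q(A, sino.omega, scheme)
        c, d = compute_c_d(mu, A, sino.omega, sino.l_hat, D, alpha, scheme,
                           p, q, patch_means=means)
        assert np.abs(c - mu).max() < 1e-10      # zero residual data target
        assert np.abs(d - mu).max() < 1e-8       # exactly coded patches

    def test_matches_dense_oracle(self, toy, rng):
        geom, A, mu, sino = toy
        scheme = PatchScheme(2, 1, 8)
        D = _exact_patch_dictionary()
        mu_t = rng.random((8, 8)) * 0.1
        X = extract_patches(mu_t, scheme)
        means = X.mean(axis=0)
        alpha = omp_batch(D, X - means[None, :], L=2)
        p, q = compute_p_q(A, sino.omega, scheme)
        c, d = compute_c_d(mu_t, A, sino.omega, sino.l_hat, D, alpha,
                           scheme, p, q, patch_means=means)
        # dense recomputation of the separable-surrogate targets
        dense = A.matrix.toarray()
        resid = dense @ mu_t.ravel() - sino.l_hat
        grad = dense.T @ (sino.omega * resid)
        c_oracle = mu_t.ravel() - grad / p
        approx = D.atoms @ alpha + means[None, :]
        acc, qcount = patch_adjoint_accumulate(approx, scheme)
        d_oracle = acc.ravel() / qcount.ravel()
        assert np.allclose(c.ravel(), c_oracle, atol=1e-10)
        assert np.allclose(d.ravel(), d_oracle, atol=1e-10)


class TestUpdates:
    def test_awr_limits_and_midpoint(self):
        c = np.array([[2.0]])
        d = np.array([[4.0]])
        assert awr_step(c, d, 0.0)[0, 0] == 2.0
        assert awr_step(c, d, math.inf)[0, 0] == 4.0
        assert awr_step(c, d, 1.0)[0, 0] == 3.0
        assert awr_step(np.array([[-1.0]]), np.array([[-2.0]]), 1.0)[0, 0] == 0.0

    def test_awr_rejects_negative_lambda(self):
        with pytest.raises(ValueError):
            awr_step(np.zeros((2, 2)), np.zeros((2, 2)), -1.0)

    def test_sir_step_matches_per_pixel_quadratic_minimizer(self, toy, rng):
        """The curvature-weighted update equals the closed-form minimizer
        of each pixel's 1-D quadratic surrogate."""
        geom, A, mu, sino = toy
        scheme = PatchScheme(2, 1, 8)
        D = _exact_patch_dictionary()
        mu_t = rng.random((8, 8)) * 0.1
        X = extract_patches(mu_t, scheme)
        means = X.mean(axis=0)
        alpha = omp_batch(D, X - means[None, :], L=2)
        lam = 0.7
        p, q = compute_p_q(A, sino.omega, scheme)
        step = sir_dl_step(mu_t, A, sino.omega, sino.l_hat, D, alpha, lam,
                           scheme, p, q, patch_means=means)
        c, d = compute_c_d(mu_t, A, sino.omega, sino.l_hat, D, alpha,
                           scheme, p, q, patch_means=means)
        # per-pixel scan of the quadratic p/2 (x-c)^2 + lam q (x-d)^2
        for j in rng.choice(64, size=12, replace=False):
            pj, qj = p[j], q[j]
            cj, dj = c.ravel()[j], d.ravel()[j]
            xs = np.linspace(-0.2, 0.4, 20001)
            vals = 0.5 * pj * (xs - cj) ** 2 + lam * qj * (xs - dj) ** 2
            x_opt = max(xs[np.argmin(vals)], 0.0)
            assert step.ravel()[j] == pytest.approx(x_opt, abs=1e-4)

    def test_sir_step_rejects_infinite_lambda(self, toy):
        geom, A, mu, sino = toy
        scheme = PatchScheme(2, 1, 8)
        D = _exact_patch_dictionary()
        alpha = np.zeros((8, PatchScheme(2, 1, 8).n_patches))
        with pytest.raises(ValueError):
            sir_dl_step(mu, A, sino.omega, sino.l_hat, D, alpha, math.inf,
                        scheme)

    def test_awr_equals_sir_under_reweighted_regularizer(self, toy, rng):
        """Replacing the patch curvature q by the reweighted p/2 makes the
        classic update algebraically identical to the AWR closed form."""
        geom, A, mu, sino = toy
        p = rng.random(64) + 0.1
        c = rng.standard_normal(64) * 0.1
        d = rng.standard_normal(64) * 0.1
        for lam in (0.0, 0.3, 1.0, 7.5):
            q_tilde = p / 2.0
            sir = np.maximum((p * c + 2 * lam * q_tilde * d)
                             / (p + 2 * lam * q_tilde), 0.0)
            awr = awr_step(c.reshape(8, 8), d.reshape(8, 8), lam).ravel()
            assert np.allclose(sir, awr, atol=1e-10)

    def test_objective_non_increasing_over_random_instances(self, rng):
        """One curvature-weighted update never increases the surrogate
        objective (data fidelity + lam * patch penalty) for fixed codes."""
        geom = ds.build_geometry(6, 60.0, 8, 6, 2.0)
        A = ds.build_system_matrix(geom)
        scheme = PatchScheme(2, 1, 6)
        D = _exact_patch_dictionary()
        worse = 0
        for _ in range(50):
            mu_true = rng.random((6, 6)) * 0.1
            sino = ds.simulate_scan(mu_true, geom, 0.0, A=A)
            mu_t = np.maximum(mu_true + 0.05 * rng.standard_normal((6, 6)),
                              0.0)
            X = extract_patches(mu_t, scheme)
            means = X.mean(axis=0)
            alpha = omp_batch(D, X - means[None, :], L=2)
            lam = float(rng.random() * 2)

            def objective(img):
                fid = 0.5 * float(np.sum(
                    sino.omega * (A.matrix @ img.ravel() - sino.l_hat) ** 2))
                patches = extract_patches(img, scheme)
                approx = D.atoms @ alpha + means[None, :]
                reg = float(((patches - approx) ** 2).sum())
                return fid + lam * reg

            nxt = sir_dl_step(mu_t, A, sino.omega, sino.l_hat, D, alpha,
                              lam, scheme, patch_means=means)
            if objective(nxt) > objective(mu_t) + 1e-9:
                worse += 1
        assert worse == 0


class TestRunReconstruction:
    def test_lambda_zero_is_dictionary_independent(self, toy):
        geom, A, mu, sino = toy
        out = []
        for seed in (1, 2):
            cfg = ReconConfig(lam=0.0, max_outer=3, n_subsets=2,
                              sart_sweeps=10, n_atoms=16,
                              ksvd_train_patches=30, patch_size=2,
                              seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out.append(run_reconstruction(sino, A, "adaptive", cfg).image)
        assert np.allclose(out[0], out[1], atol=1e-12)

    def test_global_mode_requires_dictionary(self, toy):
        geom, A, mu, sino = toy
        with pytest.raises(ValueError):
            run_reconstruction(sino, A, "global", ReconConfig())

    def test_reproducible_given_seed(self, toy):
        geom, A, mu, sino = toy
        def go():
            cfg = ReconConfig(lam=0.5, max_outer=2, n_subsets=2,
                              sart_sweeps=10, n_atoms=16,
                              ksvd_train_patches=30, patch_size=2, seed=9)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return run_reconstruction(sino, A, "adaptive", cfg).image
        assert np.array_equal(go(), go())

    def test_delta_monotone_in_lambda_with_fixed_dictionary(
            self, toy_geom32, toy_system32, phantom32):
        """Converged weighted data-fidelity error grows with lambda and
        the patch penalty shrinks (the balancing property of the
        regularization weight)."""
        from dictsir.sparse_model import train_global_dictionary
        sino = ds.simulate_scan(phantom32, toy_geom32, 0.002, seed=4,
                                A=toy_system32)
        scheme = PatchScheme(8, 1, 32)
        D = train_global_dictionary(phantom32, scheme, K=128, L=5,
                                    n_iters=15, seed=0)
        deltas, regs = [], []
        for lam in (0.1, 1.0, 10.0):
            cfg = ReconConfig(lam=lam, dictionary=D, max_outer=30,
                              n_subsets=5, code_tol=0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_reconstruction(sino, toy_system32, "global", cfg)
            X = extract_patches(res.image, scheme)
            X0 = X - X.mean(axis=0, keepdims=True)
            alpha = omp_batch(D, X0, 32, tol_rel=1e-3)
            deltas.append(res.delta)
            regs.append(float(((X0 - D.atoms @ alpha) ** 2).sum()))
        assert deltas[0] <= deltas[1] <= deltas[2]
        assert regs[0] >= regs[1] >= regs[2]


def test_weighted_delta_rejects_zero_reference():
    with pytest.raises(ValueError):
        weighted_delta(np.ones(4), np.zeros(4), np.ones(4))
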