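"""Bayesian core: KL prior, likelihood, profiled alpha, log-weight optimiser."""

import itertools

import numpy as np
import pytest
from scipy import optimize as sp_optimize

from cryoreweight.reweight import (
    WeightState,
    chi2,
    effective_sample_size,
    kl_divergence,
    neg_log_posterior,
    optimal_alpha,
    optimize_weights,
    scan_sigma_kernel,
)

from conftest import make_selection


class TestKL:
    def test_zero_iff_equal(self):
        w = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(w, w) == 0.0

    def test_concentrated_two_state_limit(self):
        eps = 1e-12
        val = kl_divergence([1 - eps, eps], [0.5, 0.5])
        assert val == pytest.approx(np.log(2), abs=1e-9)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            w = rng.dirichlet(np.ones(5))
            w0 = rng.dirichlet(np.ones(5))
            expect = sum(wi * np.log(wi / w0i) for wi, w0i in zip(w, w0))
            assert kl_divergence(w, w0) == pytest.approx(expect, abs=1e-12)

    def test_non_normalised_rejected(self):
        with pytest.raises(ValueError, match="normalis"):
            kl_divergence([0.5, 0.6], [0.5, 0.5])

    def test_nonnegative_property(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = rng.dirichlet(np.ones(4))
            w0 = rng.dirichlet(np.ones(4))
            assert kl_divergence(w, w0) >= -1e-15


class TestNeff:
    def test_closed_forms(self):
        assert effective_sample_size(0.0) == 1.0
        assert effective_sample_size(np.log(2)) == pytest.approx(0.5)

    def test_concentration_on_one_of_ten(self):
        eps = 1e-13
        w = np.full(10, eps / 9)
        w[0] = 1 - eps
        s = kl_divergence(w, np.full(10, 0.1))
        assert effective_sample_size(s) == pytest.approx(0.1, rel=1e-6)

    def test_negative_s_kl_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(-0.1)


class TestChi2:
    def test_perfect_single_model_fit(self):
        sel = make_selection([1.0, 0.5, 0.2], np.array([[1.0], [0.5], [0.2]]))
        assert chi2(sel, [1.0], alpha=1.0, sigma_L2=1.0) == 0.0

    def test_hand_arithmetic(self):
        sel = make_selection([1.0, 0.0], np.array([[0.5], [0.5]]))
        assert chi2(sel, [1.0], 1.0, 1.0) == pytest.approx(0.5)

    def test_doubling_variance_halves_chi2(self, toy_selection):
        w = [0.5, 0.5]
        assert chi2(toy_selection, w, 1.0, 2.0) == pytest.approx(
            chi2(toy_selection, w, 1.0, 1.0) / 2
        )


class TestAlpha:
    def test_exact_scale_recovered(self):
        sel = make_selection([2.0, 1.0, 0.4], np.array([[1.0], [0.5], [0.2]]))
        assert optimal_alpha(sel, [1.0]) == pytest.approx(2.0)

    def test_orthogonal_gives_zero(self):
        sel = make_selection([1.0, 0.0], np.array([[0.0], [1.0]]))
        with pytest.warns(UserWarning, match="alpha"):
            assert optimal_alpha(sel, [1.0]) == 0.0

    def test_matches_scalar_minimiser(self):
        rng = np.random.default_rng(3)
        sel = make_selection(rng.uniform(size=10), rng.uniform(size=(10, 3)))
        w = rng.dirichlet(np.ones(3))
        a_closed = optimal_alpha(sel, w)
        res = sp_optimize.minimize_scalar(
            lambda a: chi2(sel, w, a, 1.0), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-12},
        )
        assert a_closed == pytest.approx(res.x, abs=1e-8)

    def test_zero_denominator_rejected(self):
        sel = make_selection([1.0, 1.0], np.array([[0.0], [0.0]]))
        with pytest.raises(ValueError, match="zero"):
            optimal_alpha(sel, [1.0])


class TestNegLogPosterior:
    def test_value_at_prior_is_half_chi2(self, toy_selection):
        w0 = np.array([0.5, 0.5])
        alpha = optimal_alpha(toy_selection, w0)
        expect = 0.5 * chi2(toy_selection, w0, alpha, 1.0)
        for theta in (0.0, 5.0, 1e4):
            value, _ = neg_log_posterior(np.zeros(2), theta, toy_selection, w0, 1.0)
            assert value == pytest.approx(expect, rel=1e-12)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(4)
        sel = make_selection(rng.uniform(size=6), rng.uniform(size=(6, 4)))
        w0 = rng.dirichlet(np.ones(4))
        theta = 2.5
        h = 1e-6
        for _ in range(10):
            g = rng.normal(0, 0.5, size=4)
            _, grad = neg_log_posterior(g, theta, sel, w0, 1.0)
            for k in range(4):
                e = np.zeros(4)
                e[k] = h
                fp, _ = neg_log_posterior(g + e, theta, sel, w0, 1.0)
                fm, _ = neg_log_posterior(g - e, theta, sel, w0, 1.0)
                fd = (fp - fm) / (2 * h)
                assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_theta_zero_ignores_prior(self, toy_selection):
        g = np.array([0.3, -0.2])
        v1, _ = neg_log_posterior(g, 0.0, toy_selection, [0.5, 0.5], 1.0)
        # same w reached from a different prior: w0' exp(g') = w0 exp(g)
        w = WeightState.from_g(g, np.array([0.5, 0.5])).w
        w0b = np.array([0.25, 0.75])
        gb = np.log(w / w0b)
        v2, _ = neg_log_posterior(gb, 0.0, toy_selection, w0b, 1.0)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_non_finite_g_rejected(self, toy_selection):
        with pytest.raises(ValueError):
            neg_log_posterior(np.array([np.nan, 0.0]), 1.0, toy_selection, [0.5, 0.5], 1.0)


class TestOptimizeWeights:
    def test_single_member_forced_to_one(self):
        sel = make_selection([1.0, 0.5], np.array([[0.9], [0.4]]))
        out = optimize_weights(sel, [1.0], theta=3.0, sigma_L2=1.0)
        assert out.state.w[0] == 1.0
        assert out.neff == 1.0

    def test_prior_dominated_limit(self, toy_selection):
        w0 = np.array([0.3, 0.7])
        out = optimize_weights(toy_selection, w0, theta=1e9, sigma_L2=1.0)
        np.testing.assert_allclose(out.state.w, w0, atol=1e-3)

    def test_correct_model_identified_vs_grid_search(self):
        # model 0 equals the reference, model 1 orthogonal; theta = 0
        ref = np.array([1.0, 0.8, 0.6, 0.0, 0.0, 0.0])
        m1 = np.array([0.0, 0.0, 0.0, 1.0, 0.8, 0.6])
        sel = make_selection(ref, np.stack([ref, m1], axis=1))
        out = optimize_weights(sel, [0.5, 0.5], theta=0.0, sigma_L2=0.01)
        assert out.state.w[0] > 0.99
        # 1-D brute force over w1 on a 1e-4 grid
        grid = np.arange(1e-4, 1.0, 1e-4)
        chis = [
            chi2(sel, [w1, 1 - w1], optimal_alpha(sel, [w1, 1 - w1]), 0.01)
            for w1 in grid
        ]
        w1_best = grid[int(np.argmin(chis))]
        assert out.state.w[0] == pytest.approx(w1_best, abs=1e-3)

    @pytest.mark.parametrize("m,theta", [(2, 0.5), (3, 2.0)])
    def test_matches_simplex_brute_force(self, m, theta):
        rng = np.random.default_rng(10 + m)
        sel = make_selection(rng.uniform(size=8), rng.uniform(size=(8, m)))
        w0 = np.full(m, 1.0 / m)
        out = optimize_weights(sel, w0, theta=theta, sigma_L2=0.5)

        def objective(w):
            w = np.asarray(w)
            return theta * kl_divergence(w, w0) + 0.5 * chi2(
                sel, w, optimal_alpha(sel, w), 0.5
            )

        # dense simplex grid
        step = 2e-3
        best_w, best_f = None, np.inf
        if m == 2:
            for w1 in np.arange(step, 1.0, step):
                f = objective([w1, 1 - w1])
                if f < best_f:
                    best_f, best_w = f, np.array([w1, 1 - w1])
        else:
            for w1 in np.arange(step, 1.0, 5 * step):
                for w2 in np.arange(step, 1.0 - w1, 5 * step):
                    w3 = 1.0 - w1 - w2
                    if w3 <= 0:
                        continue
                    f = objective([w1, w2, w3])
                    if f < best_f:
                        best_f, best_w = f, np.array([w1, w2, w3])
            # refine locally around the coarse optimum
            res = sp_optimize.minimize(
                lambda v: objective(np.append(np.abs(v), 1 - np.abs(v).sum())),
                best_w[:2], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12},
            )
            best_w = np.append(np.abs(res.x), 1 - np.abs(res.x).sum())
        np.testing.assert_allclose(out.state.w, best_w, atol=1e-3)

    def test_weights_strictly_positive(self, toy_selection):
        out = optimize_weights(toy_selection, [0.5, 0.5], theta=0.0, sigma_L2=0.01)
        assert (out.state.w > 0).all()

    def test_profiled_alpha_equals_closed_form(self, toy_selection):
        out = optimize_weights(toy_selection, [0.5, 0.5], theta=1.0, sigma_L2=1.0)
        assert out.alpha == pytest.approx(optimal_alpha(toy_selection, out.state.w))


class TestSigmaScan:
    def _bench(self):
        from cryoreweight.synth import make_two_state_ensemble, make_mixture_reference

        ens = make_two_state_ensemble(M=6, n_residues=16, seed=3)
        ref, truth, noise = make_mixture_reference(ens, [0.5, 0.5], 8.0, 0.01, seed=4)
        return ens, ref, noise

    def test_single_value_grid_returned(self):
        ens, ref, noise = self._bench()
        sigma, sel, res = scan_sigma_kernel(ens, ref, [1.8], noise=noise)
        assert sigma == 1.8
        assert sel.sigma_kernel == 1.8

    def test_self_consistent_width_recovered(self):
        ens, ref, noise = self._bench()
        s_true = 0.225 * 8.0
        sigma, _, _ = scan_sigma_kernel(
            ens, ref, [s_true / 2, s_true, 2 * s_true], noise=noise
        )
        assert sigma == pytest.approx(s_true)

    def test_grid_order_invariance(self):
        ens, ref, noise = self._bench()
        grid = [1.0, 1.8, 2.6]
        a = scan_sigma_kernel(ens, ref, grid, noise=noise)
        b = scan_sigma_kernel(ens, ref, grid[::-1], noise=noise)
        assert a[0] == b[0]
        np.testing.assert_allclose(a[2].weights, b[2].weights, atol=1e-9)


class TestMonotoneTradeoff:
    def test_skl_and_chi2_monotone_in_theta(self):
        rng = np.random.default_rng(7)
        sel = make_selection(rng.uniform(size=12), rng.uniform(size=(12, 4)))
        w0 = np.full(4, 0.25)
        thetas = [0.0, 0.1, 1.0, 10.0, 100.0, 1e3]
        skls, chis = [], []
        for t in thetas:
            out = optimize_weights(sel, w0, t, sigma_L2=0.05)
            skls.append(out.s_kl)
            chis.append(out.chi2)
        assert all(a >= b - 1e-9 for a, b in zip(skls, skls[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(chis, chis[1:]))
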