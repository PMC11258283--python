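"""Constrained-ML core: closed forms, oracles, BIC selection, perturbation."""

from itertools import combinations

import numpy as np
import pytest
from scipy import optimize

from cismr import (
    ConditionalGWAS,
    SummarySimConfig,
    ar_ld_matrix,
    bic_scan,
    data_perturbation,
    estimate_se,
    fit_fixed_K,
    fit_marginal_model,
    loglik,
    marginal_to_conditional,
    maximize_given_support,
    simulate_summary,
)
from cismr.cml import _CMLData, _profile_loglik, _topk
from cismr.errors import DegenerateInformationError


def numeric_max_on_support(cx, cy, A, theta0=0.0, n_restarts=3, seed=0):
    """Generic-optimizer oracle: BFGS over (theta, b_X, r_A), best of restarts."""
    m, k = cx.m, len(A)
    rng = np.random.default_rng(seed)
    best = -np.inf

    def nll(par):
        r = np.zeros(m)
        r[list(A)] = par[1 + m :]
        return -loglik(par[0], par[1 : 1 + m], r, cx, cy)

    for i in range(n_restarts):
        x0 = np.concatenate([[theta0], cx.beta, np.zeros(k)])
        if i:
            x0 = x0 + rng.normal(0, 0.1, x0.size)
        res = optimize.minimize(nll, x0, method="BFGS",
                                options={"maxiter": 5000, "gtol": 1e-12})
        best = max(best, -res.fun)
    return best


def exhaustive_fixed_k(cx, cy, K):
    """Brute-force support enumeration with numerical inner maximization."""
    best_ll, best_A = -np.inf, None
    for A in combinations(range(cx.m), K):
        ll = numeric_max_on_support(cx, cy, list(A))
        if ll > best_ll:
            best_ll, best_A = ll, A
    return best_ll, best_A


class TestLoglik:
    def test_saturated_fit_is_zero(self, small_conditional):
        cx, cy, truth, cfg = small_conditional
        theta = 0.3
        r = cy.beta - theta * cx.beta
        assert loglik(theta, cx.beta, r, cx, cy) == pytest.approx(0.0, abs=1e-10)

    def test_always_nonpositive(self, small_conditional, rng):
        cx, cy, *_ = small_conditional
        for _ in range(20):
            val = loglik(
                rng.normal(), rng.normal(0, 0.1, cx.m), rng.normal(0, 0.1, cx.m), cx, cy
            )
            assert val <= 1e-12

    def test_single_snp_hand_value(self):
        # first quadratic form (1-0)^2/1 = 1 -> ll = -0.5; second term zeroed
        cx = ConditionalGWAS([1.0], [[1.0]], 100)
        cy = ConditionalGWAS([0.0], [[1.0]], 100)
        assert loglik(0.0, [0.0], [0.0], cx, cy) == pytest.approx(-0.5)


class TestMaximizeGivenSupport:
    def test_noise_free_null_support(self):
        ld = ar_ld_matrix(4, 0.5)
        bx = np.array([0.3, -0.2, 0.1, 0.25])
        theta = 0.7
        cx = ConditionalGWAS(bx, 1e-6 * np.eye(4), 1000)
        cy = ConditionalGWAS(theta * bx, 1e-6 * np.eye(4), 1000)
        fit = maximize_given_support([], cx, cy)
        assert fit.theta == pytest.approx(theta, abs=1e-6)
        np.testing.assert_allclose(fit.r, 0.0)

    def test_single_deviant_snp_recovered(self):
        bx = np.array([0.3, -0.2, 0.1, 0.25])
        theta = 0.5
        by = theta * bx
        by[2] += 0.4  # direct effect on SNP 2 only
        cx = ConditionalGWAS(bx, 1e-8 * np.eye(4), 1000)
        cy = ConditionalGWAS(by, 1e-8 * np.eye(4), 1000)
        fit = maximize_given_support([2], cx, cy)
        assert fit.theta == pytest.approx(theta, abs=1e-5)
        assert fit.r[2] == pytest.approx(0.4, abs=1e-5)
        assert fit.r[[0, 1, 3]] == pytest.approx(0.0)

    def test_matches_generic_optimizer(self, small_conditional):
        cx, cy, *_ = small_conditional
        for A in ([], [0], [3], [1, 4]):
            fit = maximize_given_support(A, cx, cy)
            oracle = numeric_max_on_support(cx, cy, A)
            assert fit.loglik >= oracle - 1e-6

    def test_monotone_flag_and_support_invariant(self, small_conditional):
        cx, cy, *_ = small_conditional
        fit = maximize_given_support([1, 2], cx, cy, theta0=0.3)
        assert fit.monotone
        off = np.setdiff1d(np.arange(cx.m), fit.invalid_set)
        np.testing.assert_allclose(fit.r[off], 0.0)


class TestFitFixedK:
    def test_k0_equals_empty_support(self, small_conditional):
        cx, cy, *_ = small_conditional
        f1 = fit_fixed_K(cx, cy, 0)
        f2 = maximize_given_support([], cx, cy)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        assert f1.theta == pytest.approx(f2.theta, abs=1e-6)

    def test_strong_pleiotropy_identified(self):
        rng = np.random.default_rng(5)
        bx = np.array([0.3, 0.2, 0.25, 0.35])
        theta = 0.2
        by = theta * bx
        by[1] += 0.5  # one strongly invalid instrument
        s2 = 1e-4
        cx = ConditionalGWAS(bx + rng.normal(0, np.sqrt(s2), 4), s2 * np.eye(4), 10_000)
        cy = ConditionalGWAS(by + rng.normal(0, np.sqrt(s2), 4), s2 * np.eye(4), 10_000)
        fit = fit_fixed_K(cx, cy, 1)
        assert list(fit.invalid_set) == [1]
        assert fit.theta == pytest.approx(theta, abs=0.05)
        ll_oracle, A_oracle = exhaustive_fixed_k(cx, cy, 1)
        assert A_oracle == (1,)
        assert fit.loglik >= ll_oracle - 1e-6

    def test_initial_ranking_is_largest_outcome_effect(self):
        # with theta0=0, b0=0 the ranking statistic is |beta_Y|; ties -> lower index
        t = np.abs(np.array([0.1, 0.5, 0.5, 0.2]))
        np.testing.assert_array_equal(_topk(t, 2), [1, 2])
        np.testing.assert_array_equal(_topk(t, 3), [1, 2, 3])

    def test_k_out_of_range(self, small_conditional):
        cx, cy, *_ = small_conditional
        with pytest.raises(ValueError):
            fit_fixed_K(cx, cy, cx.m - 1)


class TestBICScan:
    def test_noise_free_null_selects_k0(self):
        bx = np.array([0.3, -0.2, 0.1, 0.25])
        cx = ConditionalGWAS(bx, 1e-8 * np.eye(4), 10_000)
        cy = ConditionalGWAS(0.4 * bx, 1e-8 * np.eye(4), 10_000)
        res = bic_scan(cx, cy, 10_000, 10_000, seed=0)
        assert res.k_hat == 0
        assert res.theta == pytest.approx(0.4, abs=1e-4)

    def test_bic_path_matches_exhaustive_oracle(self, small_conditional):
        cx, cy, truth, cfg = small_conditional
        res = bic_scan(cx, cy, cfg.n_x, cfg.n_y, seed=3)
        logn = np.log(min(cfg.n_x, cfg.n_y))
        for K in range(0, cx.m - 1):
            ll_oracle, _ = exhaustive_fixed_k(cx, cy, K)
            assert res.fits[K].loglik >= ll_oracle - 1e-6
            assert res.bic[K] == pytest.approx(-2 * res.fits[K].loglik + logn * K)

    def test_large_pleiotropy_selects_all_invalid(self):
        """kappa=20 design: BIC identifies all four invalid IVs in most draws."""
        cfg = SummarySimConfig.scenario1(k1=4, kappa=20.0, theta=0.0)
        hits = 0
        n = 40
        for k in range(n):
            rng = np.random.default_rng([77, k])
            expo, outc, ld, truth = simulate_summary(cfg, rng=rng)
            cx = marginal_to_conditional(expo, ld)
            cy = marginal_to_conditional(outc, ld)
            res = bic_scan(cx, cy, cfg.n_x, cfg.n_y, rng=rng, compute_se=False)
            hits += res.k_hat == 4 and set(res.invalid_set) == set(truth.invalid_set)
        assert hits / n > 0.7

    def test_profile_maximizer_equivalence(self, small_conditional):
        """At convergence theta equals the profile-likelihood maximizer on the
        selected support."""
        cx, cy, truth, cfg = small_conditional
        res = bic_scan(cx, cy, cfg.n_x, cfg.n_y, seed=1)
        d = _CMLData(cx, cy)
        A = np.asarray(res.invalid_set, dtype=np.int64)
        opt = optimize.minimize_scalar(
            lambda t: -_profile_loglik(t, A, d),
            bracket=(res.theta - 0.3, res.theta + 0.3),
            method="brent", options={"xtol": 1e-12},
        )
        assert abs(res.theta - opt.x) < 1e-6


class TestEstimateSE:
    def test_single_snp_closed_form(self):
        bx_hat, by_hat, sx2, sy2 = 1.0, 0.2, 0.04, 0.01
        cx = ConditionalGWAS([bx_hat], [[sx2]], 10_000)
        cy = ConditionalGWAS([by_hat], [[sy2]], 10_000)
        fit = maximize_given_support([], cx, cy)
        # profile: l_p(t) = -(by - t bx)^2 / (2 (sy2 + t^2 sx2))
        def lp(t):
            return -0.5 * (by_hat - t * bx_hat) ** 2 / (sy2 + t**2 * sx2)
        h = 1e-5
        t0 = fit.theta
        curv = (lp(t0 + h) - 2 * lp(t0) + lp(t0 - h)) / h**2
        assert estimate_se(fit, cx, cy) == pytest.approx(np.sqrt(-1 / curv), rel=1e-4)

    def test_known_exposure_gls_limit(self):
        """Sigma_X -> 0: the SE approaches (b_X' Sigma_Y^{-1} b_X)^{-1/2}."""
        rng = np.random.default_rng(3)
        bx = rng.normal(0, 0.3, 4)
        Sy = 0.01 * ar_ld_matrix(4, 0.3).R
        cx = ConditionalGWAS(bx, 1e-12 * np.eye(4), 10_000)
        cy = ConditionalGWAS(0.5 * bx + rng.normal(0, 0.01, 4), Sy, 10_000)
        fit = maximize_given_support([], cx, cy)
        se = estimate_se(fit, cx, cy)
        gls = 1 / np.sqrt(bx @ np.linalg.inv(Sy) @ bx)
        assert se == pytest.approx(gls, rel=1e-3)

    def test_degenerate_information_raised(self):
        # b_X = 0: the profile is flat in theta at the optimum
        cx = ConditionalGWAS([0.0, 0.0, 0.0], 1e-4 * np.eye(3), 1000)
        cy = ConditionalGWAS([0.0, 0.0, 0.0], 1e-4 * np.eye(3), 1000)
        fit = maximize_given_support([], cx, cy)
        with pytest.raises(DegenerateInformationError):
            estimate_se(fit, cx, cy)


class TestDataPerturbation:
    def test_seed_reproducibility(self, small_conditional):
        cx, cy, truth, cfg = small_conditional
        dp1 = data_perturbation(cx, cy, cfg.n_x, cfg.n_y, B=10, seed=4)
        dp2 = data_perturbation(cx, cy, cfg.n_x, cfg.n_y, B=10, seed=4)
        np.testing.assert_array_equal(dp1.estimates, dp2.estimates)
        assert dp1.theta == dp2.theta and dp1.se == dp2.se

    def test_substream_stability_under_larger_B(self, small_conditional):
        cx, cy, truth, cfg = small_conditional
        dp10 = data_perturbation(cx, cy, cfg.n_x, cfg.n_y, B=10, seed=4)
        dp15 = data_perturbation(cx, cy, cfg.n_x, cfg.n_y, B=15, seed=4)
        np.testing.assert_array_equal(dp10.estimates, dp15.estimates[:10])

    def test_degenerate_perturbation_collapses(self):
        bx = np.array([0.3, -0.2, 0.1, 0.25])
        eps = 1e-12
        cx = ConditionalGWAS(bx, eps * np.eye(4), 10_000)
        cy = ConditionalGWAS(0.4 * bx, eps * np.eye(4), 10_000)
        dp = data_perturbation(cx, cy, 10_000, 10_000, B=5, seed=0)
        assert dp.se == pytest.approx(0.0, abs=1e-4)
        assert dp.theta == pytest.approx(0.4, abs=1e-4)

    def test_minimum_b(self, small_conditional):
        cx, cy, *_ = small_conditional
        with pytest.raises(ValueError):
            data_perturbation(cx, cy, 100, 100, B=1)


class TestMarginalVariant:
    def test_identity_ld_equals_conditional_fit(self, rng):
        cfg = SummarySimConfig.scenario1(m=5, k1=0, rho=0.0, theta=0.1)
        expo, outc, ld, truth = simulate_summary(cfg, rng=rng)
        cx = marginal_to_conditional(expo, ld)
        cy = marginal_to_conditional(outc, ld)
        res_c = bic_scan(cx, cy, cfg.n_x, cfg.n_y, seed=9)
        res_m = fit_marginal_model(expo, outc, ld, seed=9)
        assert res_m.theta == pytest.approx(res_c.theta, rel=1e-6)
        assert res_m.k_hat == res_c.k_hat

    def test_single_snp_region(self):
        from cismr import LDMatrix, MarginalGWAS

        ld = LDMatrix(np.eye(1), ["a"])
        expo = MarginalGWAS(["a"], [0.3], [0.01], 10_000)
        outc = MarginalGWAS(["a"], [0.15], [0.01], 10_000)
        cx = marginal_to_conditional(expo, ld)
        cy = marginal_to_conditional(outc, ld)
        res_c = bic_scan(cx, cy, 10_000, 10_000, seed=0)
        res_m = fit_marginal_model(expo, outc, ld, seed=0)
        assert res_m.theta == pytest.approx(res_c.theta, rel=1e-8)
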