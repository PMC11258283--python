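"""Comparator estimators: hand examples, GLS oracles, and the IVW identity."""

import numpy as np
import pytest

from cismr import (
    LDMatrix,
    MarginalGWAS,
    ar_ld_matrix,
    gegger,
    givw,
    legger,
    livw,
    marginal_to_conditional,
    wald_ratio,
)
from cismr.errors import DimensionMismatchError
from tests.conftest import random_marginal_pair


def _wls_oracle(y, X, w):
    """Textbook weighted least squares via normal equations (diagonal weights)."""
    W = np.diag(w)
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)


def _gls_oracle(y, X, Winv):
    """Generalized least squares with a full weight matrix."""
    W = np.linalg.inv(Winv)
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)


class TestWald:
    def test_hand_values(self):
        x = MarginalGWAS(["a"], [0.3], [0.05], 100)
        y = MarginalGWAS(["a"], [0.6], [0.1], 100)
        est = wald_ratio(x, y)
        assert est.theta == pytest.approx(2.0)
        assert est.se == pytest.approx(1 / 3)

    def test_zero_outcome(self):
        x = MarginalGWAS(["a"], [0.3], [0.05], 100)
        y = MarginalGWAS(["a"], [0.0], [0.1], 100)
        assert wald_ratio(x, y).theta == 0.0

    def test_zero_exposure_rejected(self):
        x = MarginalGWAS(["a"], [0.0], [0.05], 100)
        y = MarginalGWAS(["a"], [0.6], [0.1], 100)
        with pytest.raises(ZeroDivisionError):
            wald_ratio(x, y)

    def test_requires_single_snp(self):
        x = MarginalGWAS(["a", "b"], [0.3, 0.2], [0.05, 0.05], 100)
        with pytest.raises(DimensionMismatchError):
            wald_ratio(x, x)


class TestGIVW:
    def test_exact_linear_relation(self, rng):
        ld = ar_ld_matrix(5, 0.5)
        bx = rng.normal(0, 0.2, 5)
        x = MarginalGWAS(ld.snp_ids, bx, rng.uniform(0.01, 0.1, 5), 1000)
        y = MarginalGWAS(ld.snp_ids, 2 * bx, rng.uniform(0.01, 0.1, 5), 1000)
        assert givw(x, y, ld).theta == pytest.approx(2.0, abs=1e-10)

    def test_hand_2x2_gls(self, ld2):
        x = MarginalGWAS(["rs1", "rs2"], [0.5, 0.25], [1.0, 1.0], 1000)
        y = MarginalGWAS(["rs1", "rs2"], [1.2, 0.5], [1.0, 1.0], 1000)
        est = givw(x, y, ld2)
        # oracle: explicit GLS with Omega = R (unit se)
        oracle = _gls_oracle(y.beta_star, x.beta_star[:, None], ld2.R)[0]
        assert est.theta == pytest.approx(oracle, rel=1e-12)
        assert est.theta == pytest.approx(2.4, rel=1e-9)

    def test_single_snp_equals_wald(self):
        ld1 = LDMatrix(np.eye(1), ["a"])
        x = MarginalGWAS(["a"], [0.3], [0.05], 100)
        y = MarginalGWAS(["a"], [0.6], [0.1], 100)
        assert givw(x, y, ld1).theta == pytest.approx(wald_ratio(x, y).theta)

    def test_diagonal_reduces_to_classical_ivw(self, rng):
        m = 6
        ld = LDMatrix(np.eye(m), [f"s{i}" for i in range(m)])
        x = MarginalGWAS(ld.snp_ids, rng.normal(0, 0.2, m), rng.uniform(0.02, 0.1, m), 500)
        y = MarginalGWAS(ld.snp_ids, rng.normal(0, 0.2, m), rng.uniform(0.02, 0.1, m), 500)
        est = givw(x, y, ld)
        oracle = _wls_oracle(y.beta_star, x.beta_star[:, None], y.se_star**-2)[0]
        assert est.theta == pytest.approx(oracle, rel=1e-10)

    def test_permutation_invariance(self, rng):
        expo, outc, ld = random_marginal_pair(rng, m=5)
        perm = rng.permutation(5)
        t1 = givw(expo, outc, ld).theta
        t2 = givw(expo.subset(perm), outc.subset(perm), ld.subset(perm)).theta
        assert t1 == pytest.approx(t2, rel=1e-10)


class TestEgger:
    def test_exact_affine_recovery(self, rng):
        m = 5
        ld = LDMatrix(np.eye(m), [f"s{i}" for i in range(m)])
        bx = np.abs(rng.normal(0.2, 0.1, m))  # positive: orientation is a no-op
        x = MarginalGWAS(ld.snp_ids, bx, np.ones(m), 1000)
        y = MarginalGWAS(ld.snp_ids, 0.1 + 2 * bx, np.ones(m), 1000)
        est = gegger(x, y, ld)
        assert est.theta == pytest.approx(2.0, abs=1e-9)
        assert est.intercept == pytest.approx(0.1, abs=1e-9)

    def test_hand_ols(self):
        ld = LDMatrix(np.eye(3), list("abc"))
        x = MarginalGWAS(list("abc"), [1.0, 2.0, 3.0], [1, 1, 1], 100)
        y = MarginalGWAS(list("abc"), [1.0, 2.0, 4.0], [1, 1, 1], 100)
        est = gegger(x, y, ld)
        assert est.theta == pytest.approx(1.5)
        assert est.intercept == pytest.approx(-2 / 3)

    def test_minimum_three_snps(self, ld2):
        x = MarginalGWAS(["rs1", "rs2"], [0.5, 0.25], [1, 1], 100)
        with pytest.raises(DimensionMismatchError):
            gegger(x, x, ld2)

    def test_orientation_invariance_to_coding(self, rng):
        """Flipping a SNP's allele coding leaves the oriented fit unchanged."""
        expo, outc, ld = random_marginal_pair(rng, m=5)
        est1 = gegger(expo, outc, ld)
        s = np.array([1, -1, 1, -1, 1.0])
        expo2 = MarginalGWAS(ld.snp_ids, s * expo.beta_star, expo.se_star, expo.n)
        outc2 = MarginalGWAS(ld.snp_ids, s * outc.beta_star, outc.se_star, outc.n)
        ld_f = LDMatrix(ld.R * np.outer(s, s), ld.snp_ids)
        est2 = gegger(expo2, outc2, ld_f)
        assert est1.theta == pytest.approx(est2.theta, rel=1e-10)
        assert est1.intercept == pytest.approx(est2.intercept, rel=1e-10)


class TestLDAware:
    def test_identity_ld_equals_classical(self, rng):
        m = 5
        ld = LDMatrix(np.eye(m), [f"s{i}" for i in range(m)])
        expo = MarginalGWAS(ld.snp_ids, rng.normal(0, 0.2, m), rng.uniform(0.02, 0.1, m), 500)
        outc = MarginalGWAS(ld.snp_ids, rng.normal(0, 0.2, m), rng.uniform(0.02, 0.1, m), 500)
        cx = marginal_to_conditional(expo, ld)
        cy = marginal_to_conditional(outc, ld)
        assert livw(cx, cy).theta == pytest.approx(givw(expo, outc, ld).theta, rel=1e-10)
        assert legger(cx, cy).theta == pytest.approx(gegger(expo, outc, ld).theta, rel=1e-10)

    def test_livw_equals_givw_identity(self, rng):
        """The LD-aware and generalized IVW point estimates coincide (100 draws)."""
        for _ in range(100):
            expo, outc, ld = random_marginal_pair(rng, m=5, rho=0.5)
            cx = marginal_to_conditional(expo, ld)
            cy = marginal_to_conditional(outc, ld)
            assert abs(livw(cx, cy).theta - givw(expo, outc, ld).theta) < 1e-8

    def test_exact_proportionality(self, ld2):
        x = MarginalGWAS(["rs1", "rs2"], [0.5, 0.25], [0.1, 0.1], 1000)
        cx = marginal_to_conditional(x, ld2)
        cy = type(cx)(beta=3.0 * cx.beta, Sigma=cx.Sigma, n=1000)
        assert livw(cx, cy).theta == pytest.approx(3.0, abs=1e-10)

    def test_legger_against_gls_oracle(self, rng):
        expo, outc, ld = random_marginal_pair(rng, m=4, rho=0.4)
        cx = marginal_to_conditional(expo, ld)
        cy = marginal_to_conditional(outc, ld)
        est = legger(cx, cy)
        s = np.where(cx.beta < 0, -1.0, 1.0)
        X = np.column_stack([np.ones(4), s * cx.beta])
        coef = _gls_oracle(s * cy.beta, X, cy.Sigma * np.outer(s, s))
        assert est.intercept == pytest.approx(coef[0], rel=1e-9)
        assert est.theta == pytest.approx(coef[1], rel=1e-9)

    def test_legger_conditional_affine(self):
        from cismr import ConditionalGWAS

        bx = np.array([0.2, 0.4, 0.1, 0.5])
        cx = ConditionalGWAS(bx, np.eye(4), 1000)
        cy = ConditionalGWAS(0.1 + 2 * bx, np.eye(4), 1000)
        est = legger(cx, cy)
        assert est.theta == pytest.approx(2.0, abs=1e-9)
        assert est.intercept == pytest.approx(0.1, abs=1e-9)
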