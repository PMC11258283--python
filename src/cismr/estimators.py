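"""Comparator cis-MR estimators: Wald ratio, generalized IVW/Egger, LD-aware IVW/Egger.

Two families are provided. The *generalized* estimators (``givw``, ``gegger``)
work on marginal GWAS effects and weight by the inverse of
``Omega_Y = R * se_Y se_Y^T``, the covariance of the marginal outcome
estimates. The *LD-aware* estimators (``livw``, ``legger``) apply the same
generalized least-squares formulas to conditional estimates, weighting by
``Sigma_Y^{-1}``. The IVW point estimates of the two families coincide
algebraically; the Egger ones in general do not. With a diagonal LD matrix
all four reduce to the classical independent-instrument IVW/Egger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DimensionMismatchError, SingularLDError
from .summary_data import ConditionalGWAS, LDMatrix, MarginalGWAS, regularize_ld


@dataclass
class CausalEstimate:
    """A causal-effect estimate with its uncertainty.

    ``intercept``/``intercept_se`` are populated only by the Egger variants,
    where a non-zero intercept indicates directional pleiotropy.
    """

    theta: float
    se: float
    p: float
    method: str
    m_used: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self):
        if self.se is not None and not (self.se > 0 or np.isnan(self.se)):
            raise ValueError("standard error must be positive")


def _pvalue(z: float, df: int | None = None) -> float:
    if df is not None:
        return float(2 * stats.t.sf(abs(z), df))
    return float(2 * stats.norm.sf(abs(z)))


def wald_ratio(exposure: MarginalGWAS, outcome: MarginalGWAS) -> CausalEstimate:
    """Single-instrument ratio estimate ``beta_Y / beta_X``.

    The standard error is first-order delta method, ``se_Y / |beta_X|``,
    ignoring exposure uncertainty as is conventional for a strong instrument.
    """
    if exposure.m != 1 or outcome.m != 1:
        raise DimensionMismatchError("wald_ratio requires exactly one SNP")
    bx = float(exposure.beta_star[0])
    if bx == 0:
        raise ZeroDivisionError("exposure effect is zero; Wald ratio undefined")
    theta = float(outcome.beta_star[0]) / bx
    se = float(outcome.se_star[0]) / abs(bx)
    return CausalEstimate(theta, se, _pvalue(theta / se), "wald", 1)


def _omega_y(outcome: MarginalGWAS, ld: LDMatrix) -> np.ndarray:
    ld = regularize_ld(ld)
    Omega = ld.R * np.outer(outcome.se_star, outcome.se_star)
    w = np.linalg.eigvalsh(Omega)
    if w.min() <= 0:
        raise SingularLDError(
            f"marginal covariance singular (min eigenvalue {w.min():.3e})"
        )
    return Omega


def _gls(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    random_effects: bool,
):
    """Generalized WLS of y on columns of X with weight matrix W.

    Returns coefficients, their covariance (scaled by the multiplicative
    overdispersion ``phi = max(1, Pearson residual variance)`` when
    ``random_effects``), and phi.
    """
    XtW = X.T @ W
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ y)
    resid = y - X @ coef
    dof = y.shape[0] - X.shape[1]
    phi = 1.0
    if random_effects and dof > 0:
        phi = max(1.0, float(resid @ W @ resid) / dof)
    cov = phi * np.linalg.inv(A)
    return coef, cov, phi


def givw(
    exposure: MarginalGWAS,
    outcome: MarginalGWAS,
    ld: LDMatrix,
    random_effects: bool = True,
    t_dist: bool = False,
) -> CausalEstimate:
    """Generalized IVW on marginal estimates with weight ``Omega_Y^{-1}``."""
    if not (exposure.m == outcome.m == ld.m):
        raise DimensionMismatchError("exposure, outcome and LD must match")
    W = np.linalg.inv(_omega_y(outcome, ld))
    X = exposure.beta_star[:, None]
    coef, cov, _ = _gls(outcome.beta_star, X, W, random_effects)
    theta = float(coef[0])
    se = float(np.sqrt(cov[0, 0]))
    df = exposure.m - 1 if (t_dist and exposure.m > 1) else None
    return CausalEstimate(theta, se, _pvalue(theta / se, df), "givw", exposure.m)


def _orient_positive(beta_x, beta_y, M):
    """Flip SNP signs so all exposure effects are non-negative.

    Egger regression is not invariant to allele coding; the convention here
    (and in the generalized Egger implementations it mirrors) makes every
    exposure effect non-negative, applying the same sign flips to the outcome
    effects and to the rows/columns of the weight-defining matrix ``M``.
    """
    s = np.where(beta_x < 0, -1.0, 1.0)
    return s * beta_x, s * beta_y, M * np.outer(s, s)


def _egger(beta_x, beta_y, M, m, method, random_effects, t_dist):
    if m < 3:
        raise DimensionMismatchError(f"{method} requires at least 3 SNPs, got {m}")
    bx, by, Mo = _orient_positive(beta_x, beta_y, M)
    W = np.linalg.inv(Mo)
    X = np.column_stack([np.ones(m), bx])
    coef, cov, _ = _gls(by, X, W, random_effects)
    theta, alpha = float(coef[1]), float(coef[0])
    se = float(np.sqrt(cov[1, 1]))
    se_a = float(np.sqrt(cov[0, 0]))
    df = m - 2 if t_dist else None
    return CausalEstimate(
        theta,
        se,
        _pvalue(theta / se, df),
        method,
        m,
        intercept=alpha,
        intercept_se=se_a,
        intercept_p=_pvalue(alpha / se_a, df),
    )


def gegger(
    exposure: MarginalGWAS,
    outcome: MarginalGWAS,
    ld: LDMatrix,
    random_effects: bool = True,
    t_dist: bool = False,
) -> CausalEstimate:
    """Generalized Egger regression on marginal estimates (slope + intercept)."""
    if not (exposure.m == outcome.m == ld.m):
        raise DimensionMismatchError("exposure, outcome and LD must match")
    Omega = _omega_y(outcome, ld)
    return _egger(
        exposure.beta_star,
        outcome.beta_star,
        Omega,
        exposure.m,
        "gegger",
        random_effects,
        t_dist,
    )


def livw(
    expo_cond: ConditionalGWAS,
    outc_cond: ConditionalGWAS,
    random_effects: bool = True,
    t_dist: bool = False,
) -> CausalEstimate:
    """LD-aware IVW on conditional estimates, weighted by ``Sigma_Y^{-1}``.

    The point estimate is algebraically identical to :func:`givw` applied to
    the marginal data that generated the conditional inputs.
    """
    if expo_cond.m != outc_cond.m:
        raise DimensionMismatchError("conditional inputs must match")
    W = np.linalg.inv(outc_cond.Sigma)
    X = expo_cond.beta[:, None]
    coef, cov, _ = _gls(outc_cond.beta, X, W, random_effects)
    theta = float(coef[0])
    se = float(np.sqrt(cov[0, 0]))
    df = expo_cond.m - 1 if (t_dist and expo_cond.m > 1) else None
    return CausalEstimate(theta, se, _pvalue(theta / se, df), "livw", expo_cond.m)


def legger(
    expo_cond: ConditionalGWAS,
    outc_cond: ConditionalGWAS,
    random_effects: bool = True,
    t_dist: bool = False,
) -> CausalEstimate:
    """LD-aware Egger regression on conditional estimates."""
    if expo_cond.m != outc_cond.m:
        raise DimensionMismatchError("conditional inputs must match")
    return _egger(
        expo_cond.beta,
        outc_cond.beta,
        outc_cond.Sigma,
        expo_cond.m,
        "legger",
        random_effects,
        t_dist,
    )
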