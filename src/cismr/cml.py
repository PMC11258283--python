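"""Constrained maximum likelihood for cis-MR with correlated instruments.

The model treats the conditional effect estimates as multivariate normal,

    beta_X_hat ~ MVN(b_X, Sigma_X)
    beta_Y_hat ~ MVN(theta * b_X + r, Sigma_Y),

where ``theta`` is the causal effect of the exposure on the outcome, ``b_X``
the conditional SNP-exposure effects, and ``r`` the horizontal-pleiotropy
(direct) effects. The log-likelihood, up to constants, is

    l = -1/2 [ (bX_hat - b_X)' Sigma_X^{-1} (bX_hat - b_X)
             + (bY_hat - theta b_X - r)' Sigma_Y^{-1} (bY_hat - theta b_X - r) ].

For a candidate number of invalid instruments ``K`` the likelihood is
maximized subject to ``r`` having exactly ``K`` non-zero entries, by
iteratively re-ranking SNPs on their estimated pleiotropy and running
block-coordinate ascent on the active support (each block update is an exact
generalized-least-squares step, so ascent is guaranteed). ``K`` is selected
by BIC(K) = -2 l + log(min(N_X, N_Y)) * K. Inference uses either the profile
-likelihood observed Fisher information at the selected support, or data
perturbation: resampling the conditional estimates from their sampling
distribution, re-running the full selection-and-fit pipeline, and reading the
estimate and its standard error off the perturbed fits.

The numerical kernels are JIT-compiled with numba; a ``NUMBA_DISABLE_JIT``
environment variable falls back to pure numpy for debugging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .errors import (
    ConvergenceError,
    DegenerateInformationError,
    DimensionMismatchError,
)
from .summary_data import ConditionalGWAS, LDMatrix, MarginalGWAS, regularize_ld

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 200
DEFAULT_MAX_OUTER = 100
DEFAULT_N_STARTS = 5
DEFAULT_START_WIDTH = 0.5
DEFAULT_B = 100
DEFAULT_THETA_BOUND = 10.0


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ll(theta, bx, r, bx_hat, by_hat, Sx_inv, Sy_inv):
    dx = bx_hat - bx
    dy = by_hat - theta * bx - r
    return -0.5 * (dx @ (Sx_inv @ dx) + dy @ (Sy_inv @ dy))


@njit(cache=True)
def _topk(t, K):
    """Indices of the K largest entries of t; ties keep the lower index."""
    m = t.shape[0]
    sel = np.empty(K, dtype=np.int64)
    used = np.zeros(m, dtype=np.bool_)
    for j in range(K):
        best = -1
        bestv = -np.inf
        for i in range(m):
            if not used[i] and t[i] > bestv:
                bestv = t[i]
                best = i
        used[best] = True
        sel[j] = best
    return np.sort(sel)


@njit(cache=True)
def _inner_solve(bx_hat, by_hat, Sx_inv, Sy_inv, A, theta, bx, r):
    """Exact joint maximizer of the likelihood over (b_X, r_A) at fixed theta.

    Solves the stationarity system (the single-block GLS updates
    b_X <- (Sx_inv + theta^2 Sy_inv)^{-1} (Sx_inv bX_hat + theta Sy_inv (bY_hat - r))
    and r_A <- ((Sy_inv)_AA)^{-1} (Sy_inv (bY_hat - theta b_X))_A hold jointly
    at its solution). Writes into ``bx`` and ``r`` in place.
    """
    m = bx_hat.shape[0]
    k = A.shape[0]
    M = np.empty((m + k, m + k))
    rhs = np.empty(m + k)
    t2 = theta * theta
    for i in range(m):
        for j in range(m):
            M[i, j] = Sx_inv[i, j] + t2 * Sy_inv[i, j]
    sy_by = Sy_inv @ by_hat
    sx_bx = Sx_inv @ bx_hat
    for i in range(m):
        rhs[i] = sx_bx[i] + theta * sy_by[i]
    for a in range(k):
        ia = A[a]
        rhs[m + a] = sy_by[ia]
        for j in range(m):
            M[j, m + a] = theta * Sy_inv[j, ia]
            M[m + a, j] = theta * Sy_inv[ia, j]
        for b in range(k):
            M[m + a, m + b] = Sy_inv[ia, A[b]]
    sol = np.linalg.solve(M, rhs)
    for i in range(m):
        bx[i] = sol[i]
    r[:] = 0.0
    for a in range(k):
        r[A[a]] = sol[m + a]


@njit(cache=True)
def _profile_ll(bx_hat, by_hat, Sx_inv, Sy_inv, A, theta, bx, r):
    """Profile log-likelihood at theta (inner parameters written in place)."""
    _inner_solve(bx_hat, by_hat, Sx_inv, Sy_inv, A, theta, bx, r)
    return _ll(theta, bx, r, bx_hat, by_hat, Sx_inv, Sy_inv)


@njit(cache=True)
def _ascent(bx_hat, by_hat, Sx_inv, Sy_inv, A, theta0, bx0, r0, tol, max_iter,
            bound):
    """Maximize the likelihood on support A by ascent on the theta-profile.

    The inner parameters (b_X, r_A) are profiled out exactly at every trial
    theta, so the problem reduces to one dimension; theta moves by a
    safeguarded (backtracking) Newton step on the profile log-likelihood,
    with finite-difference derivatives. Backtracking only ever accepts an
    increase, so the likelihood sequence is non-decreasing. Coordinate-wise
    single-block updates reach the same fixed points but zigzag badly when
    instruments are weak (flat profile); the profiled Newton ascent is the
    same maximization, just conditioned better.

    ``bound`` restricts theta to [-bound, bound]: when the selected valid set
    carries no exposure signal the profile increases toward a flat plateau at
    |theta| -> inf, and the restriction keeps such non-identified fits finite
    (they are reported at the boundary).
    """
    m = bx_hat.shape[0]
    theta = min(max(theta0, -bound), bound)
    bx = bx0.copy()
    r = r0.copy()
    # likelihood at the start values themselves (before any inner solve)
    ll_start = _ll(theta, bx, r, bx_hat, by_hat, Sx_inv, Sy_inv)
    f0 = _profile_ll(bx_hat, by_hat, Sx_inv, Sy_inv, A, theta, bx, r)
    monotone = f0 >= ll_start - 1e-8
    converged = False
    n_iter = 0
    bx_t = np.empty(m)
    r_t = np.empty(m)
    for it in range(max_iter):
        n_iter = it + 1
        h = 1e-5 * max(1.0, abs(theta))
        fp = _profile_ll(bx_hat, by_hat, Sx_inv, Sy_inv, A, theta + h, bx_t, r_t)
        fm = _profile_ll(bx_hat, by_hat, Sx_inv, Sy_inv, A, theta - h, bx_t, r_t)
        grad = (fp - fm) / (2.0 * h)
        curv = (fp - 2.0 * f0 + fm) / (h * h)
        if curv < 0.0:
            step = -grad / curv
        else:
            step = np.sign(grad) * max(1.0, abs(theta))
        cap = 10.0 * max(1.0, abs(theta))
        if abs(step) > cap:
            step = np.sign(step) * cap
        step = min(max(theta + step, -bound), bound) - theta
        if step == 0.0:
            converged = True
            break
        f1 = f0
        accepted = False
        for _bt in range(40):
            f1 = _profile_ll(
                bx_hat, by_hat, Sx_inv, Sy_inv, A, theta + step, bx_t, r_t
            )
            if f1 >= f0:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        theta = theta + step
        bx[:] = bx_t
        r[:] = r_t
        if f1 - f0 < tol:
            f0 = f1
            converged = True
            break
        f0 = f1
    return theta, bx, r, f0, n_iter, converged, monotone


@njit(cache=True)
def _swap_refine(bx_hat, by_hat, Sx_inv, Sy_inv, theta, bx, r, A, ll,
                 tol, max_iter, bound):
    """Single-swap local search on the invalid-instrument support.

    The support re-ranking heuristic can settle one element away from the
    best subset; exchanging each in-support index against each out-of-support
    index (re-maximizing from the current parameters, accepting only
    improvements) repairs that at modest cost. Terminates when no swap
    improves the likelihood.
    """
    m = bx_hat.shape[0]
    K = A.shape[0]
    if K == 0 or K >= m:
        return theta, bx, r, A, ll
    n_swaps = K * (m - K)
    bx_t = np.empty(m)
    r_t = np.empty(m)
    scores = np.empty(n_swaps)
    cand = np.empty((n_swaps, K), dtype=np.int64)
    for _round in range(20):
        # screen every swap by the exact profile value at the current theta
        # (a lower bound on the swapped support's maximum)
        s = 0
        for ai in range(K):
            for j in range(m):
                in_support = False
                for aj in range(K):
                    if A[aj] == j:
                        in_support = True
                        break
                if in_support:
                    continue
                A_try = A.copy()
                A_try[ai] = j
                A_try = np.sort(A_try)
                cand[s] = A_try
                scores[s] = _profile_ll(
                    bx_hat, by_hat, Sx_inv, Sy_inv, A_try, theta, bx_t, r_t
                )
                s += 1
        # full re-maximization only for the top-scoring few candidates
        order = np.argsort(-scores[:s])
        improved = False
        for q in range(min(3, s)):
            A_try = cand[order[q]]
            th, b, rr, ll2, _ni, _cv, _mo = _ascent(
                bx_hat, by_hat, Sx_inv, Sy_inv, A_try, theta, bx,
                r * 0.0, tol, max_iter, bound,
            )
            if ll2 > ll + 1e-10:
                theta, bx, r, A, ll = th, b, rr, A_try.copy(), ll2
                improved = True
                break
        if not improved:
            break
    return theta, bx, r, A, ll


@njit(cache=True)
def _scan_kernel(bx_hat, by_hat, Sx_inv, Sy_inv, Sy_diag, k_arr, theta0s, bx0s,
                 tol, max_iter, max_outer, bound):
    """Best-of-starts constrained fit for every candidate K in one JIT region.

    ``theta0s`` has shape (nK, n_starts); ``bx0s`` (nK, n_starts, m). Returns
    padded per-K results (support padded with -1 beyond K entries).
    """
    nK = k_arr.shape[0]
    m = bx_hat.shape[0]
    n_starts = theta0s.shape[1]
    kmax = 0
    for i in range(nK):
        kmax = max(kmax, k_arr[i])
    thetas = np.empty(nK)
    bxs = np.empty((nK, m))
    rs = np.empty((nK, m))
    A_pad = np.full((nK, max(kmax, 1)), -1, dtype=np.int64)
    lls = np.full(nK, -np.inf)
    iters = np.zeros(nK, dtype=np.int64)
    convs = np.zeros(nK, dtype=np.bool_)
    monos = np.ones(nK, dtype=np.bool_)
    for i in range(nK):
        K = k_arr[i]
        for s in range(n_starts):
            th, bx, r, A, ll, ni, conv, mono = _fit_fixed_k_kernel(
                bx_hat, by_hat, Sx_inv, Sy_inv, Sy_diag, K,
                theta0s[i, s], bx0s[i, s].copy(), tol, max_iter, max_outer,
                bound,
            )
            iters[i] += ni
            if ll > lls[i]:
                lls[i] = ll
                thetas[i] = th
                bxs[i] = bx
                rs[i] = r
                for a in range(K):
                    A_pad[i, a] = A[a]
                convs[i] = conv
                monos[i] = mono
        if 0 < K < m:
            th, bx, r, A, ll = _swap_refine(
                bx_hat, by_hat, Sx_inv, Sy_inv, thetas[i], bxs[i], rs[i],
                A_pad[i, :K].copy(), lls[i], tol, max_iter, bound,
            )
            if ll > lls[i]:
                lls[i] = ll
                thetas[i] = th
                bxs[i] = bx
                rs[i] = r
                for a in range(K):
                    A_pad[i, a] = A[a]
                convs[i] = np.abs(th) < bound - 1e-9
    return thetas, bxs, rs, A_pad, lls, iters, convs, monos


@njit(cache=True)
def _same_support(a, b):
    if a.shape[0] != b.shape[0]:
        return False
    for i in range(a.shape[0]):
        if a[i] != b[i]:
            return False
    return True


@njit(cache=True)
def _fit_fixed_k_kernel(
    bx_hat, by_hat, Sx_inv, Sy_inv, Sy_diag, K, theta0, bx0, tol, max_iter,
    max_outer, bound
):
    """Iterative support re-ranking around the block-ascent inner maximizer.

    Initial support: K largest |beta_Y_hat - theta0 * bx0|. After each
    accepted maximization the SNPs are re-ranked on the squared residual
    pleiotropy (beta_Y_hat - theta b_X)^2 / diag(Sigma_Y) and the support
    reset to the top K; the loop stops when the support stabilizes or no
    longer improves the likelihood.
    """
    m = bx_hat.shape[0]
    t0 = np.abs(by_hat - theta0 * bx0)
    A_cur = _topk(t0, K)
    # likelihood of the plug-in initial state (r set to the raw residual on A)
    r_init = np.zeros(m)
    resid0 = by_hat - theta0 * bx0
    for a in range(K):
        r_init[A_cur[a]] = resid0[A_cur[a]]
    L_best = _ll(theta0, bx0, r_init, bx_hat, by_hat, Sx_inv, Sy_inv)
    theta = theta0
    bx = bx0.copy()
    r_best = r_init.copy()
    A_best = A_cur.copy()
    converged = False
    monotone = True
    total_iter = 0
    for _outer in range(max_outer):
        th, b, r, ll, ni, conv, mono = _ascent(
            bx_hat, by_hat, Sx_inv, Sy_inv, A_cur, theta, bx, r_best * 0.0,
            tol, max_iter, bound
        )
        total_iter += ni
        if not mono:
            monotone = False
        if ll > L_best:
            L_best = ll
            theta = th
            bx = b
            r_best = r
            A_best = A_cur.copy()
            tstat = (by_hat - th * b) ** 2 / Sy_diag
            A_new = _topk(tstat, K)
            if _same_support(A_new, A_cur):
                converged = conv
                break
            A_cur = A_new
        else:
            converged = True
            break
    return theta, bx, r_best, A_best, L_best, total_iter, converged, monotone


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class CMLFit:
    """A constrained-ML fit at one fixed number of invalid instruments."""

    theta: float
    b_x: np.ndarray
    r: np.ndarray
    invalid_set: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    monotone: bool = True

    @property
    def k(self) -> int:
        return int(self.invalid_set.shape[0])


@dataclass
class CMLResult:
    """BIC path over candidate K with the selected fit and its inference."""

    fits: dict
    bic: dict
    k_hat: int
    theta: float
    se: float
    p: float
    valid_set: np.ndarray = field(default=None)

    @property
    def invalid_set(self) -> np.ndarray:
        return self.fits[self.k_hat].invalid_set


@dataclass
class DPResult:
    """Data-perturbation inference: spread of the estimate across resamples."""

    estimates: np.ndarray
    theta: float
    se: float
    p: float
    b: int
    invalid_frequency: np.ndarray
    n_fail: int = 0


class _CMLData:
    """Cached inverses and factorizations shared by every fit on one dataset."""

    def __init__(self, expo_cond: ConditionalGWAS, outc_cond: ConditionalGWAS):
        if expo_cond.m != outc_cond.m:
            raise DimensionMismatchError("exposure and outcome dimensions differ")
        self.m = expo_cond.m
        self.bx_hat = np.ascontiguousarray(expo_cond.beta)
        self.by_hat = np.ascontiguousarray(outc_cond.beta)
        self.Sx = expo_cond.Sigma
        self.Sy = outc_cond.Sigma
        self.Sx_inv = np.ascontiguousarray(np.linalg.inv(self.Sx))
        self.Sy_inv = np.ascontiguousarray(np.linalg.inv(self.Sy))
        self.Sx_inv = 0.5 * (self.Sx_inv + self.Sx_inv.T)
        self.Sy_inv = 0.5 * (self.Sy_inv + self.Sy_inv.T)
        self.Sy_diag = np.ascontiguousarray(np.diag(self.Sy))
        self._Lx = None
        self._Ly = None

    def chol(self):
        if self._Lx is None:
            self._Lx = np.linalg.cholesky(self.Sx)
            self._Ly = np.linalg.cholesky(self.Sy)
        return self._Lx, self._Ly

    def perturbed(self, zx, zy) -> "_CMLData":
        Lx, Ly = self.chol()
        new = _CMLData.__new__(_CMLData)
        new.m = self.m
        new.bx_hat = self.bx_hat + Lx @ zx
        new.by_hat = self.by_hat + Ly @ zy
        new.Sx, new.Sy = self.Sx, self.Sy
        new.Sx_inv, new.Sy_inv = self.Sx_inv, self.Sy_inv
        new.Sy_diag = self.Sy_diag
        new._Lx, new._Ly = self._Lx, self._Ly
        return new


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def loglik(
    theta: float,
    b_x: np.ndarray,
    r: np.ndarray,
    expo_cond: ConditionalGWAS,
    outc_cond: ConditionalGWAS,
) -> float:
    """Model log-likelihood (constants dropped); always <= 0."""
    d = _CMLData(expo_cond, outc_cond)
    b_x = np.asarray(b_x, dtype=float)
    r = np.asarray(r, dtype=float)
    if b_x.shape != (d.m,) or r.shape != (d.m,):
        raise DimensionMismatchError("b_x and r must have length m")
    return float(_ll(float(theta), b_x, r, d.bx_hat, d.by_hat, d.Sx_inv, d.Sy_inv))


def maximize_given_support(
    support,
    expo_cond: ConditionalGWAS,
    outc_cond: ConditionalGWAS,
    theta0: float = 0.0,
    bx0: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    theta_bound: float = DEFAULT_THETA_BOUND,
) -> CMLFit:
    """Maximize the likelihood with ``r`` restricted to the index set ``support``."""
    d = _CMLData(expo_cond, outc_cond)
    A = np.asarray(sorted(support), dtype=np.int64)
    if A.size and (A.min() < 0 or A.max() >= d.m):
        raise IndexError("support indices out of range")
    if A.size > max(d.m - 2, 0):
        raise ValueError(f"support size {A.size} exceeds max(m - 2, 0) = {max(d.m - 2, 0)}")
    bx0 = np.zeros(d.m) if bx0 is None else np.asarray(bx0, dtype=float)
    theta, bx, r, ll, n_iter, conv, mono = _ascent(
        d.bx_hat, d.by_hat, d.Sx_inv, d.Sy_inv, A, float(theta0), bx0,
        np.zeros(d.m), tol, max_iter, theta_bound,
    )
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite likelihood during coordinate ascent")
    return CMLFit(float(theta), bx, r, A, float(ll), bool(conv), int(n_iter), bool(mono))


def _fit_fixed_k_data(d: _CMLData, K, theta0, bx0, tol, max_iter, max_outer,
                      theta_bound=DEFAULT_THETA_BOUND) -> CMLFit:
    theta, bx, r, A, ll, n_iter, conv, mono = _fit_fixed_k_kernel(
        d.bx_hat, d.by_hat, d.Sx_inv, d.Sy_inv, d.Sy_diag,
        int(K), float(theta0), np.asarray(bx0, dtype=float),
        tol, max_iter, max_outer, theta_bound,
    )
    if 0 < K < d.m:
        th2, bx2, r2, A2, ll2 = _swap_refine(
            d.bx_hat, d.by_hat, d.Sx_inv, d.Sy_inv, theta, bx, r, A, ll,
            tol, max_iter, theta_bound,
        )
        if ll2 > ll:
            theta, bx, r, A, ll = th2, bx2, r2, A2, ll2
            conv = abs(theta) < theta_bound - 1e-9
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite likelihood in constrained fit")
    return CMLFit(float(theta), bx, r, A, float(ll), bool(conv), int(n_iter), bool(mono))


def fit_fixed_K(
    expo_cond: ConditionalGWAS,
    outc_cond: ConditionalGWAS,
    K: int,
    theta0: float = 0.0,
    bx0: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    max_outer: int = DEFAULT_MAX_OUTER,
    theta_bound: float = DEFAULT_THETA_BOUND,
) -> CMLFit:
    """Constrained-ML fit with exactly ``K`` invalid instruments (support search)."""
    d = _CMLData(expo_cond, outc_cond)
    if not 0 <= K <= max(d.m - 2, 0):
        raise ValueError(f"K must lie in [0, {max(d.m - 2, 0)}], got {K}")
    bx0 = np.zeros(d.m) if bx0 is None else bx0
    return _fit_fixed_k_data(d, K, theta0, bx0, tol, max_iter, max_outer, theta_bound)


def _profile_loglik(theta: float, A: np.ndarray, d: _CMLData) -> float:
    """Profile log-likelihood in theta: exact inner maximization over (b_X, r_A)."""
    m, k = d.m, A.shape[0]
    Sy_inv = d.Sy_inv
    M = np.empty((m + k, m + k))
    M[:m, :m] = d.Sx_inv + theta**2 * Sy_inv
    rhs = np.empty(m + k)
    rhs[:m] = d.Sx_inv @ d.bx_hat + theta * (Sy_inv @ d.by_hat)
    if k:
        M[:m, m:] = theta * Sy_inv[:, A]
        M[m:, :m] = theta * Sy_inv[A, :]
        M[m:, m:] = Sy_inv[np.ix_(A, A)]
        rhs[m:] = (Sy_inv @ d.by_hat)[A]
    sol = np.linalg.solve(M, rhs)
    r = np.zeros(m)
    r[A] = sol[m:]
    return float(_ll(theta, sol[:m], r, d.bx_hat, d.by_hat, d.Sx_inv, d.Sy_inv))


def estimate_se(
    fit: CMLFit,
    expo_cond: ConditionalGWAS,
    outc_cond: ConditionalGWAS,
    h: float = 1e-4,
) -> float:
    """Profile-likelihood standard error at the fitted causal estimate.

    The observed Fisher information is the negative second derivative of the
    profile log-likelihood l_p(theta), where b_X and the pleiotropy effects on
    the fixed invalid set are profiled out in closed form; the derivative is a
    central finite difference with step ``h * max(1, |theta|)``.
    """
    d = _CMLData(expo_cond, outc_cond)
    A = np.asarray(fit.invalid_set, dtype=np.int64)
    step = h * max(1.0, abs(fit.theta))
    lp = [_profile_loglik(fit.theta + s, A, d) for s in (-step, 0.0, step)]
    curv = (lp[0] - 2 * lp[1] + lp[2]) / step**2
    if not np.isfinite(curv) or curv >= 0:
        raise DegenerateInformationError(
            f"profile-likelihood curvature {curv:.3e} is not negative"
        )
    return float(np.sqrt(-1.0 / curv))


def _scan(d: _CMLData, n, k_set, n_starts, start_width, rng,
          tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER, max_outer=DEFAULT_MAX_OUTER,
          theta_bound=DEFAULT_THETA_BOUND):
    """Best-of-starts fit per K and the BIC path; shared by public entry points."""
    k_arr = np.asarray(list(k_set), dtype=np.int64)
    nK = k_arr.shape[0]
    # first start per K is the deterministic (0, 0); the rest are random
    theta0s = np.zeros((nK, n_starts + 1))
    bx0s = np.zeros((nK, n_starts + 1, d.m))
    if n_starts > 0:
        Lx, _ = d.chol()
        for i in range(nK):
            for s in range(1, n_starts + 1):
                theta0s[i, s] = rng.uniform(-start_width, start_width)
                bx0s[i, s] = d.bx_hat + Lx @ rng.standard_normal(d.m)
    thetas, bxs, rs, A_pad, lls, iters, convs, monos = _scan_kernel(
        d.bx_hat, d.by_hat, d.Sx_inv, d.Sy_inv, d.Sy_diag, k_arr,
        theta0s, bx0s, tol, max_iter, max_outer, theta_bound,
    )
    # a maximizer at the boundary is a non-identified plateau, not a converged fit
    at_bound = np.abs(thetas) >= theta_bound - 1e-9
    convs = convs & ~at_bound
    if not np.all(np.isfinite(lls)):
        raise FloatingPointError("non-finite likelihood in BIC scan")
    fits, bics = {}, {}
    logn = np.log(n)
    for i, K in enumerate(k_arr):
        K = int(K)
        fits[K] = CMLFit(
            float(thetas[i]), bxs[i], rs[i], A_pad[i, :K].copy(),
            float(lls[i]), bool(convs[i]), int(iters[i]), bool(monos[i]),
        )
        bics[K] = -2.0 * float(lls[i]) + logn * K
    k_hat = min(fits, key=lambda K: (bics[K], K))
    return fits, bics, k_hat


def bic_scan(
    expo_cond: ConditionalGWAS,
    outc_cond: ConditionalGWAS,
    n_x: int,
    n_y: int,
    k_set=None,
    n_starts: int = DEFAULT_N_STARTS,
    start_width: float = DEFAULT_START_WIDTH,
    seed=None,
    rng: np.random.Generator | None = None,
    compute_se: bool = True,
) -> CMLResult:
    """Fit every candidate K, select by BIC, and return the final inference.

    Each K uses the default start (theta=0, b_X=0) plus ``n_starts`` random
    starts with theta ~ U(-start_width, start_width) and b_X drawn from the
    sampling distribution of the conditional exposure estimates. BIC uses
    N = min(n_x, n_y). Ties in BIC resolve to the smaller K.
    """
    d = _CMLData(expo_cond, outc_cond)
    kmax = max(d.m - 2, 0)
    if k_set is None:
        k_set = range(0, kmax + 1)
    k_set = sorted(set(int(k) for k in k_set))
    if not k_set or min(k_set) < 0 or max(k_set) > kmax:
        raise ValueError(f"k_set must be a nonempty subset of [0, {kmax}]")
    if rng is None:
        rng = np.random.default_rng(seed)
    fits, bics, k_hat = _scan(d, min(n_x, n_y), k_set, n_starts, start_width, rng)
    if not any(f.converged for f in fits.values()):
        raise ConvergenceError("no constrained fit converged for any candidate K")
    sel = fits[k_hat]
    theta = sel.theta
    se = p = np.nan
    if compute_se:
        se = estimate_se(sel, expo_cond, outc_cond)
        p = float(2 * stats.norm.sf(abs(theta / se)))
    valid = np.setdiff1d(np.arange(d.m), sel.invalid_set)
    return CMLResult(fits=fits, bic=bics, k_hat=k_hat, theta=theta, se=se, p=p,
                     valid_set=valid)


def data_perturbation(
    expo_cond: ConditionalGWAS,
    outc_cond: ConditionalGWAS,
    n_x: int,
    n_y: int,
    B: int = DEFAULT_B,
    seed=0,
    k_set=None,
    n_starts: int = DEFAULT_N_STARTS,
    start_width: float = DEFAULT_START_WIDTH,
) -> DPResult:
    """Model-selection-aware inference by perturbing the conditional estimates.

    For each of ``B`` perturbations the exposure and outcome estimates are
    resampled from MVN(beta_hat, Sigma), the full BIC scan re-run, and the
    mean and standard deviation of the perturbed causal estimates reported.
    Perturbation ``b`` uses the substream ``(seed, b)``, so results for the
    first B draws do not change when B is increased.
    """
    if B < 2:
        raise ValueError("data perturbation requires B >= 2")
    d = _CMLData(expo_cond, outc_cond)
    if k_set is None:
        k_set = range(0, max(d.m - 2, 0) + 1)
    k_set = sorted(set(int(k) for k in k_set))
    n = min(n_x, n_y)
    thetas = []
    invalid_counts = np.zeros(d.m)
    n_fail = 0
    for b in range(B):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, b])
        db = d.perturbed(rng.standard_normal(d.m), rng.standard_normal(d.m))
        try:
            fits, bics, k_hat = _scan(db, n, k_set, n_starts, start_width, rng)
            fit = fits[k_hat]
            if not np.isfinite(fit.loglik):
                raise FloatingPointError("non-finite likelihood")
        except (np.linalg.LinAlgError, FloatingPointError):
            n_fail += 1
            continue
        thetas.append(fit.theta)
        invalid_counts[fit.invalid_set] += 1
    if n_fail > B / 2:
        raise ConvergenceError(f"{n_fail}/{B} perturbed fits failed")
    thetas = np.asarray(thetas)
    theta = float(thetas.mean())
    se = float(thetas.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(theta / se))) if se > 0 else (0.0 if theta else 1.0)
    return DPResult(
        estimates=thetas,
        theta=theta,
        se=se,
        p=p,
        b=B,
        invalid_frequency=invalid_counts / max(len(thetas), 1),
        n_fail=n_fail,
    )


def fit_marginal_model(
    expo: MarginalGWAS,
    outc: MarginalGWAS,
    ld: LDMatrix,
    k_set=None,
    n_starts: int = DEFAULT_N_STARTS,
    start_width: float = DEFAULT_START_WIDTH,
    seed=None,
    rng: np.random.Generator | None = None,
) -> CMLResult:
    """Run the constrained-ML machinery on *marginal* estimates (diagnostic variant).

    The marginal analogue replaces the conditional inputs by
    (beta_star, Omega = R * se se^T). Under LD a single true direct effect
    spreads across the marginal effects of every correlated SNP, so the
    plurality condition that identifies the causal parameter is easily
    violated; the variant is provided to reproduce that failure mode, not for
    applied use.
    """
    Rreg = regularize_ld(ld)
    ex = ConditionalGWAS(
        beta=expo.beta_star,
        Sigma=Rreg.R * np.outer(expo.se_star, expo.se_star),
        n=expo.n,
        snp_ids=list(expo.snp_ids),
    )
    oy = ConditionalGWAS(
        beta=outc.beta_star,
        Sigma=Rreg.R * np.outer(outc.se_star, outc.se_star),
        n=outc.n,
        snp_ids=list(outc.snp_ids),
    )
    return bic_scan(
        ex, oy, expo.n, outc.n, k_set=k_set, n_starts=n_starts,
        start_width=start_width, seed=seed, rng=rng,
    )
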