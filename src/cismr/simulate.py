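"""Synthetic data generators for the two benchmark designs.

``simulate_summary`` draws GWAS summary statistics directly: conditional
exposure effects on a chosen instrument set, direct (pleiotropic) outcome
effects on another, both scaled to target variance-explained fractions, and
marginal estimates sampled around ``R @ b`` with LD-correlated noise.
``simulate_individual`` builds genotype matrices for three disjoint cohorts
via a Gaussian-copula discretization with autoregressive latent correlation,
generates phenotypes from the structural model

    X = sum_i bX_i G_i + U + eps_X,
    Y = theta X + sum_i r_i G_i + U + eps_Y,

with a shared standard-normal confounder U, and exposes a per-SNP GWAS scan
to produce summary statistics from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DimensionMismatchError
from .summary_data import LDMatrix, MarginalGWAS


def ar_ld_matrix(m: int, rho: float) -> LDMatrix:
    """Autoregressive LD: ``R[i, j] = rho ** |i - j|`` (positive definite for |rho|<1)."""
    if not abs(rho) < 1:
        raise ValueError("AR parameter must satisfy |rho| < 1")
    idx = np.arange(m)
    R = rho ** np.abs(np.subtract.outer(idx, idx))
    return LDMatrix(R, [f"snp{i + 1}" for i in range(m)])


def block_ld_matrix(m_x: int, m_y: int, rho: float, rho_xy: float) -> LDMatrix:
    """Two AR(rho) blocks with a constant cross-block correlation ``rho_xy``."""
    m = m_x + m_y
    R = np.full((m, m), float(rho_xy))
    R[:m_x, :m_x] = ar_ld_matrix(m_x, rho).R
    R[m_x:, m_x:] = ar_ld_matrix(m_y, rho).R
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise ValueError(
            f"block LD matrix with rho={rho}, rho_xy={rho_xy} is indefinite"
        )
    return LDMatrix(R, [f"snp{i + 1}" for i in range(m)])


@dataclass
class SummarySimConfig:
    """Generative parameters for the direct summary-statistic design.

    Defaults are the benchmark design: m=10 SNPs under AR(0.6) LD, all
    instruments exposure-associated, exposure variance explained
    ``h2_x = 0.05``, direct-effect share ``h2_y = 0.05``, GWAS sample sizes
    ``n_x = 10000`` and ``n_y = 50000``.

    ``i_x`` / ``i_y`` are the index sets of exposure-associated and
    direct-effect SNPs (``i_x`` defaults to all m). When ``kappa`` is set the
    direct effects are fixed at ``kappa / sqrt(n_y)`` (the weakly-invalid
    regime) instead of being scaled to ``h2_y``. ``block_sizes`` switches the
    LD matrix to two AR blocks with cross-correlation ``rho_xy``.

    ``h2_scale`` chooses which effect vector the variance-explained targets
    normalize: ``"marginal"`` scales the marginal effects ``R @ b`` to squared
    norm h2 (the convention that reproduces the benchmark instrument-strength
    values); ``"conditional"`` scales the conditional effects to
    ``b' R b = h2``.
    """

    m: int = 10
    i_x: tuple | None = None
    i_y: tuple = ()
    rho: float = 0.6
    rho_xy: float = 0.0
    block_sizes: tuple | None = None
    h2_x: float = 0.05
    h2_y: float = 0.05
    theta: float = 0.0
    n_x: int = 10_000
    n_y: int = 50_000
    kappa: float | None = None
    h2_scale: str = "marginal"
    seed: int | None = None

    def __post_init__(self):
        if self.i_x is None:
            self.i_x = tuple(range(self.m))
        self.i_x = tuple(sorted(set(int(i) for i in self.i_x)))
        self.i_y = tuple(sorted(set(int(i) for i in self.i_y)))
        for s in (self.i_x, self.i_y):
            if s and (min(s) < 0 or max(s) >= self.m):
                raise ValueError("instrument sets must be subsets of range(m)")
        if not 0 < self.h2_x < 1:
            raise ValueError("h2_x must lie in (0, 1)")
        if not 0 <= self.h2_y < 1:
            raise ValueError("h2_y must lie in [0, 1)")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.h2_scale not in ("marginal", "conditional"):
            raise ValueError("h2_scale must be 'marginal' or 'conditional'")

    @property
    def k1(self) -> int:
        """Number of invalid instruments among the exposure-associated SNPs."""
        return len(set(self.i_x) & set(self.i_y))

    @property
    def k2(self) -> int:
        """Number of direct-effect SNPs with no exposure effect."""
        return len(set(self.i_y) - set(self.i_x))

    @classmethod
    def scenario1(cls, k1: int = 0, **kw) -> "SummarySimConfig":
        """All 10 SNPs exposure-associated; the first ``k1`` also pleiotropic."""
        m = kw.pop("m", 10)
        return cls(m=m, i_x=tuple(range(m)), i_y=tuple(range(k1)), **kw)

    @classmethod
    def scenario2(cls, k1: int = 0, k2: int = 2, **kw) -> "SummarySimConfig":
        """Half the SNPs exposure-associated, ``k2`` outcome-only SNPs adjacent."""
        m = kw.pop("m", 10)
        mx = m // 2
        i_y = tuple(range(k1)) + tuple(range(mx, mx + k2))
        return cls(m=m, i_x=tuple(range(mx)), i_y=i_y, **kw)


@dataclass
class SimTruth:
    """Realized generative truth for recovery checks."""

    b_x: np.ndarray
    r: np.ndarray
    b_y: np.ndarray
    R: np.ndarray
    theta: float
    h2_x_realized: float = 0.0
    h2_y_realized: float = 0.0

    @property
    def invalid_set(self) -> np.ndarray:
        return np.flatnonzero(self.r != 0)


def _scale_to_h2(v: np.ndarray, R: np.ndarray, h2: float, h2_scale: str) -> np.ndarray:
    if h2_scale == "conditional":
        denom = float(v @ R @ v)
    else:
        Rv = R @ v
        denom = float(Rv @ Rv)
    return v * np.sqrt(h2 / denom)


def simulate_summary(cfg: SummarySimConfig, rng: np.random.Generator | None = None):
    """Draw one replicate of summary statistics under ``cfg``.

    Steps: (1) conditional exposure effects ~ N(0,1) on ``i_x``, scaled per
    ``h2_scale``; (2) direct effects ~ N(0,1) on ``i_y`` scaled to ``h2_y``
    (or fixed at ``kappa/sqrt(n_y)``); (3) outcome effects
    ``b_Y = theta b_X + r``; (4)-(5) marginal estimates
    ``beta* ~ MVN(R b, sigma*^2 R)`` with ``sigma*_X^2 = (1-h2_x)/n_x`` and
    ``sigma*_Y^2 = (1 - theta^2 h2_x - h2_y) / n_y``.

    Returns ``(exposure, outcome, ld, truth)``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.block_sizes is not None:
        ld = block_ld_matrix(cfg.block_sizes[0], cfg.block_sizes[1], cfg.rho, cfg.rho_xy)
        if ld.m != cfg.m:
            raise DimensionMismatchError("block sizes must sum to m")
    else:
        ld = ar_ld_matrix(cfg.m, cfg.rho)
    R = ld.R
    L = np.linalg.cholesky(R)

    b_x = np.zeros(cfg.m)
    b_x[list(cfg.i_x)] = rng.standard_normal(len(cfg.i_x))
    b_x = _scale_to_h2(b_x, R, cfg.h2_x, cfg.h2_scale)

    r = np.zeros(cfg.m)
    if cfg.i_y:
        if cfg.kappa is not None:
            r[list(cfg.i_y)] = cfg.kappa / np.sqrt(cfg.n_y)
        else:
            r[list(cfg.i_y)] = rng.standard_normal(len(cfg.i_y))
            r = _scale_to_h2(r, R, cfg.h2_y, cfg.h2_scale)
    b_y = cfg.theta * b_x + r

    h2_y_direct = float(r @ R @ r)
    var_y = 1.0 - cfg.theta**2 * cfg.h2_x - (cfg.h2_y if (cfg.i_y and cfg.kappa is None) else h2_y_direct)
    if var_y <= 0:
        raise ValueError(
            f"residual outcome variance 1 - theta^2 h2_x - h2_y = {var_y:.3g} <= 0"
        )
    s_x = np.sqrt((1.0 - cfg.h2_x) / cfg.n_x)
    s_y = np.sqrt(var_y / cfg.n_y)

    beta_x_star = R @ b_x + L @ rng.normal(0.0, s_x, cfg.m)
    beta_y_star = R @ b_y + L @ rng.normal(0.0, s_y, cfg.m)

    exposure = MarginalGWAS(ld.snp_ids, beta_x_star, np.full(cfg.m, s_x), cfg.n_x)
    outcome = MarginalGWAS(ld.snp_ids, beta_y_star, np.full(cfg.m, s_y), cfg.n_y)
    truth = SimTruth(
        b_x=b_x, r=r, b_y=b_y, R=R, theta=cfg.theta,
        h2_x_realized=float(b_x @ R @ b_x), h2_y_realized=h2_y_direct,
    )
    return exposure, outcome, ld, truth


@dataclass
class IndividualSimConfig:
    """Parameters for the individual-level design on synthetic genotypes.

    Cohort sizes default to the benchmark design (exposure GWAS 10000,
    outcome GWAS 100000, LD reference panel 5000); the cis-region width
    defaults to 50 SNPs. ``maf`` may be a scalar, a length-m vector, or None
    (drawn uniformly from [0.05, 0.5]). ``b_x``/``r`` may be given as full
    length-m vectors; when None, 7 exposure SNPs with effects
    ~ Unif(+/-[0.1, 0.2]) and 2 nearby pleiotropic SNPs with effects
    ~ Unif(0.1, 0.2) are sampled, keeping pairwise latent correlations of the
    chosen instruments below 0.95.
    """

    n_x: int = 10_000
    n_y: int = 100_000
    n_ref: int = 5_000
    m: int = 50
    maf: float | np.ndarray | None = None
    genotype_rho: float = 0.6
    b_x: np.ndarray | None = None
    r: np.ndarray | None = None
    theta: float = 0.0
    seed: int | None = None


def _tetrachoric_coeffs(z1, z2, order=16):
    """Coefficients c_k with corr(I{Z1<z1}, I{Z2<z2}) = sum_k c_k rho^k.

    Hermite-series expansion of the bivariate-normal orthant probability;
    accurate for |rho| <= 0.95 at modest order.
    """
    from numpy.polynomial.hermite_e import hermeval
    from scipy.special import factorial

    p1, p2 = stats.norm.cdf(z1), stats.norm.cdf(z2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    c = np.empty(order)
    for k in range(1, order + 1):
        e = np.zeros(k)
        e[-1] = 1.0  # He_{k-1}
        c[k - 1] = (
            stats.norm.pdf(z1) * stats.norm.pdf(z2)
            * hermeval(z1, e) * hermeval(z2, e) / factorial(k)
        )
    return c / denom


def _latent_correlation(target, z1, z2):
    """Invert the tetrachoric series: latent rho giving indicator corr ``target``."""
    from scipy.optimize import brentq

    c = _tetrachoric_coeffs(z1, z2)
    powers = np.arange(1, c.size + 1)

    def f(rho):
        return float(c @ rho**powers) - target

    lo, hi = -0.999, 0.999
    if target >= 0 and f(hi) < 0:
        return hi
    if target < 0 and f(lo) > 0:
        return lo
    return brentq(f, lo, hi, xtol=1e-10)


def _copula_genotypes(n, m, maf, rho, rng):
    """Genotypes ~ Binomial(2, maf) with target AR(rho) LD on the genotype scale.

    Each haplotype is a thresholded Gaussian vector; the latent correlation
    for every SNP pair is chosen by inverting the thresholding attenuation so
    the realized genotype correlations match the AR target.
    """
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (m,))
    thr = stats.norm.ppf(maf)
    idx = np.arange(m)
    target = rho ** np.abs(np.subtract.outer(idx, idx))
    latent = np.eye(m)
    cache = {}
    for i in range(m):
        for j in range(i + 1, m):
            key = (round(target[i, j], 12), round(thr[i], 6), round(thr[j], 6))
            if key not in cache:
                cache[key] = _latent_correlation(target[i, j], thr[i], thr[j])
            latent[i, j] = latent[j, i] = cache[key]
    w, V = np.linalg.eigh(latent)
    L = V * np.sqrt(np.maximum(w, 1e-10))
    G = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        z = rng.standard_normal((n, m)) @ L.T
        G += (z < thr).astype(np.int8)
    return G


def _sample_effects(cfg: IndividualSimConfig, rng):
    b_x = np.zeros(cfg.m)
    r = np.zeros(cfg.m)
    latent_R = ar_ld_matrix(cfg.m, cfg.genotype_rho).R
    for _ in range(100):
        i_x = np.sort(rng.choice(cfg.m, size=min(7, cfg.m), replace=False))
        near = np.unique(np.clip(i_x[:, None] + np.array([-2, -1, 1, 2]), 0, cfg.m - 1))
        near = np.setdiff1d(near, i_x)
        if near.size < 2:
            continue
        i_y = np.sort(rng.choice(near, size=2, replace=False))
        sel = np.union1d(i_x, i_y)
        sub = np.abs(latent_R[np.ix_(sel, sel)])
        np.fill_diagonal(sub, 0.0)
        if sub.max() < 0.95:
            break
    b_x[i_x] = rng.uniform(0.1, 0.2, i_x.size) * rng.choice([-1.0, 1.0], i_x.size)
    r[i_y] = rng.uniform(0.1, 0.2, i_y.size)
    return b_x, r


def simulate_individual(cfg: IndividualSimConfig, rng: np.random.Generator | None = None):
    """Generate genotypes for three disjoint cohorts and phenotypes for two.

    Returns a dict with keys ``G_x``, ``G_y``, ``G_ref`` (genotype matrices),
    ``X``, ``Y`` (phenotypes of the exposure and outcome cohorts) and
    ``truth`` (a :class:`SimTruth` with the latent AR matrix as ``R``).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.maf is None:
        maf = rng.uniform(0.05, 0.5, cfg.m)
    else:
        maf = np.broadcast_to(np.asarray(cfg.maf, dtype=float), (cfg.m,)).copy()
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("minor-allele frequencies must lie in (0, 0.5]")

    if cfg.b_x is None or cfg.r is None:
        b_x, r = _sample_effects(cfg, rng)
        if cfg.b_x is not None:
            b_x = np.asarray(cfg.b_x, dtype=float)
        if cfg.r is not None:
            r = np.asarray(cfg.r, dtype=float)
    else:
        b_x = np.asarray(cfg.b_x, dtype=float)
        r = np.asarray(cfg.r, dtype=float)

    out = {}
    phen = {}
    for name, n in (("x", cfg.n_x), ("y", cfg.n_y), ("ref", cfg.n_ref)):
        G = _copula_genotypes(n, cfg.m, maf, cfg.genotype_rho, rng)
        out[f"G_{name}"] = G
        if name == "ref":
            continue
        Gf = G.astype(float)
        U = rng.standard_normal(n)
        X = Gf @ b_x + U + rng.standard_normal(n)
        Y = cfg.theta * X + Gf @ r + U + rng.standard_normal(n)
        phen[name] = (X, Y)
    out["X"] = phen["x"][0]
    out["Y"] = phen["y"][1]
    out["truth"] = SimTruth(
        b_x=b_x, r=r, b_y=cfg.theta * b_x + r,
        R=ar_ld_matrix(cfg.m, cfg.genotype_rho).R, theta=cfg.theta,
    )
    return out


def ld_from_genotypes(G: np.ndarray, snp_ids=None) -> LDMatrix:
    """Empirical correlation matrix of a genotype matrix (reference panel)."""
    R = np.corrcoef(np.asarray(G, dtype=float), rowvar=False)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(R.shape[0])]
    return LDMatrix(R, snp_ids)


def gwas_scan(genotypes: np.ndarray, phenotype: np.ndarray, n_label: int | None = None):
    """Per-SNP simple linear regression of the phenotype on standardized genotype.

    The genotype is standardized (so slopes are per genotype-SD); the
    phenotype is centered but left on its own scale — use
    :func:`cismr.summary_data.standardize_marginal` afterwards to move to the
    standardized-trait scale the estimators expect. Monomorphic SNPs have no
    defined slope; they are excluded from the returned :class:`MarginalGWAS`
    and their indices reported alongside.

    Returns
    -------
    (gwas, excluded) : MarginalGWAS and the list of excluded SNP positions.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = G.shape
    if n <= 2:
        raise ValueError("GWAS scan needs more than 2 individuals")
    if y.shape[0] != n:
        raise DimensionMismatchError("phenotype length does not match genotypes")
    y = y - y.mean()
    sd = G.std(axis=0, ddof=0)
    poly = sd > 0
    Gs = (G[:, poly] - G[:, poly].mean(axis=0)) / sd[poly]
    beta = Gs.T @ y / n
    resid_var = np.maximum(
        (y @ y - n * beta**2) / (n - 2), np.finfo(float).tiny
    )
    se = np.sqrt(resid_var / n)
    ids = [f"snp{i + 1}" for i in np.flatnonzero(poly)]
    gwas = MarginalGWAS(ids, beta, se, n if n_label is None else n_label)
    return gwas, list(np.flatnonzero(~poly))
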