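"""Region-restricted GWAS summary statistics and the marginal/conditional transformation.

A GWAS reports, for each SNP *i* in a cis-region, the *marginal* regression
effect ``beta_star[i]`` of the SNP on a standardized trait together with its
standard error. When SNPs are in linkage disequilibrium (LD) with correlation
matrix ``R``, the vector of marginal effects relates to the joint/conditional
effects ``beta`` (all SNPs fitted together) through ``beta_star = R @ beta``.
Every estimator in this package consumes either the marginal statistics
directly or their conditional transform::

    beta  = R^{-1} @ beta_star
    Sigma = R^{-1} @ (R * se_star se_star^T) @ R^{-1}

where ``*`` is the element-wise product and ``Sigma`` is the covariance of the
conditional estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DimensionMismatchError,
    InvalidSampleSizeError,
    NoCommonSNPsError,
    SingularLDError,
)

logger = logging.getLogger(__name__)

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class MarginalGWAS:
    """Marginal per-SNP summary statistics for one trait in one region.

    Parameters
    ----------
    snp_ids : sequence of str
        SNP identifiers in file (genomic) order; this order is canonical.
    beta_star : array, shape (m,)
        Marginal effect estimates on the standardized-trait scale.
    se_star : array, shape (m,)
        Standard errors of ``beta_star``; strictly positive.
    n : int
        GWAS sample size (>= 3).
    a1, a2 : sequence of str, optional
        Effect and other allele codes, used only for harmonization.
    freq, p : array, optional
        Effect-allele frequency and marginal p-value, carried through from
        ``.ma`` files but not required by any estimator.
    """

    snp_ids: list
    beta_star: np.ndarray
    se_star: np.ndarray
    n: int
    a1: list | None = None
    a2: list | None = None
    freq: np.ndarray | None = None
    p: np.ndarray | None = None

    def __post_init__(self):
        self.snp_ids = list(self.snp_ids)
        self.beta_star = np.asarray(self.beta_star, dtype=float)
        self.se_star = np.asarray(self.se_star, dtype=float)
        m = len(self.snp_ids)
        if m < 1:
            raise DimensionMismatchError("at least one SNP required")
        for name in ("beta_star", "se_star"):
            v = getattr(self, name)
            if v.shape != (m,):
                raise DimensionMismatchError(
                    f"{name} has shape {v.shape}, expected ({m},)"
                )
        if np.any(self.se_star <= 0) or not np.all(np.isfinite(self.se_star)):
            raise ValueError("se_star must be strictly positive and finite")
        if int(self.n) < 3:
            raise InvalidSampleSizeError(f"sample size n={self.n} < 3")
        self.n = int(self.n)
        if self.a1 is not None:
            self.a1 = [str(a).upper() for a in self.a1]
        if self.a2 is not None:
            self.a2 = [str(a).upper() for a in self.a2]

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def subset(self, idx) -> "MarginalGWAS":
        """Return statistics restricted to the integer positions ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return MarginalGWAS(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta_star=self.beta_star[idx],
            se_star=self.se_star[idx],
            n=self.n,
            a1=[self.a1[i] for i in idx] if self.a1 is not None else None,
            a2=[self.a2[i] for i in idx] if self.a2 is not None else None,
            freq=self.freq[idx] if self.freq is not None else None,
            p=self.p[idx] if self.p is not None else None,
        )


@dataclass
class LDMatrix:
    """SNP correlation matrix from a reference panel, with matching id order."""

    R: np.ndarray
    snp_ids: list

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.snp_ids = list(self.snp_ids)
        m = len(self.snp_ids)
        if self.R.shape != (m, m):
            raise DimensionMismatchError(
                f"LD matrix shape {self.R.shape} does not match {m} SNP ids"
            )
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric (tol 1e-10)")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(self.R) > 1 + 1e-8):
            raise ValueError("LD entries must lie in [-1, 1]")
        if np.linalg.eigvalsh(self.R).min() < -1e-8:
            raise ValueError("LD matrix must be positive semi-definite")

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def subset(self, idx) -> "LDMatrix":
        idx = np.asarray(idx, dtype=int)
        return LDMatrix(self.R[np.ix_(idx, idx)], [self.snp_ids[i] for i in idx])


@dataclass
class ConditionalGWAS:
    """Joint/conditional effect estimates with their full covariance."""

    beta: np.ndarray
    Sigma: np.ndarray
    n: int
    snp_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        m = self.beta.shape[0]
        if self.Sigma.shape != (m, m):
            raise DimensionMismatchError(
                f"Sigma shape {self.Sigma.shape} does not match beta length {m}"
            )
        if not self.snp_ids:
            self.snp_ids = [f"snp{i + 1}" for i in range(m)]
        if len(self.snp_ids) != m:
            raise DimensionMismatchError("snp_ids length does not match beta")
        self.Sigma = 0.5 * (self.Sigma + self.Sigma.T)
        self.n = int(self.n)

    @property
    def m(self) -> int:
        return self.beta.shape[0]

    def subset(self, idx) -> "ConditionalGWAS":
        idx = np.asarray(idx, dtype=int)
        return ConditionalGWAS(
            self.beta[idx],
            self.Sigma[np.ix_(idx, idx)],
            self.n,
            [self.snp_ids[i] for i in idx],
        )


def standardize_marginal(beta_star, se_star, n):
    """Rescale marginal GWAS effects to the standardized-trait/genotype scale.

    Implements ``beta_std = beta_star / sqrt(beta_star^2 + (n - 2) se_star^2)``
    and returns the implied standardized-scale standard error
    ``sqrt((1 - beta_std^2) / n)`` (floored at variance 0, capped at 1/n).
    The GWAS never states a standardized SE; this convention matches the
    variance model used by the summary-statistic simulator.

    Returns
    -------
    (beta_std, se_std) : pair of arrays (or scalars, matching the input)
    """
    if int(n) < 3:
        raise InvalidSampleSizeError(f"standardization requires n >= 3, got {n}")
    beta_star = np.asarray(beta_star, dtype=float)
    se_star = np.asarray(se_star, dtype=float)
    if np.any(se_star <= 0):
        raise ValueError("se_star must be strictly positive")
    beta_std = beta_star / np.sqrt(beta_star**2 + (n - 2) * se_star**2)
    var_std = np.clip(1.0 - beta_std**2, 0.0, 1.0) / n
    se_std = np.sqrt(np.maximum(var_std, np.finfo(float).tiny))
    if np.isscalar(beta_star) or beta_std.ndim == 0:
        return float(beta_std), float(se_std)
    return beta_std, se_std


def regularize_ld(ld: LDMatrix, min_eig: float = 1e-6) -> LDMatrix:
    """Floor the eigenvalues of an LD matrix at ``min_eig`` and restore unit diagonal.

    Reference-panel correlation matrices are frequently near-singular; the
    marginal-to-conditional transformation needs an inverse, so eigenvalues
    below ``min_eig`` are raised to ``min_eig`` and the result rescaled back to
    a correlation matrix. Well-conditioned input is returned unchanged.
    """
    if np.linalg.eigvalsh(ld.R).min() >= min_eig:
        return ld
    R = ld.R
    for _ in range(10):  # unit-diagonal rescaling can undercut the floor slightly
        w, V = np.linalg.eigh(R)
        if w.min() >= min_eig:
            break
        w = np.maximum(w, min_eig * 1.05)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = 0.5 * (R + R.T)
        np.fill_diagonal(R, 1.0)
    return LDMatrix(R, ld.snp_ids)


def marginal_to_conditional(
    marg: MarginalGWAS, ld: LDMatrix, min_eig: float = 1e-6
) -> ConditionalGWAS:
    """Transform marginal summary statistics to conditional estimates.

    ``beta = R^{-1} beta_star`` and ``Sigma = R^{-1} (R * s s^T) R^{-1}`` with
    ``s = se_star``. The LD matrix is regularized first; if it remains
    numerically singular a :class:`SingularLDError` is raised naming the
    offending minimum eigenvalue.
    """
    if ld.m != marg.m or ld.snp_ids != marg.snp_ids:
        if ld.m != marg.m:
            raise DimensionMismatchError(
                f"LD matrix is {ld.m}x{ld.m} but GWAS has {marg.m} SNPs"
            )
        raise DimensionMismatchError("SNP id order differs between GWAS and LD matrix")
    ld = regularize_ld(ld, min_eig=min_eig)
    R = ld.R
    w = np.linalg.eigvalsh(R)
    if w.min() <= max(min_eig * 1e-3, 1e-12):
        raise SingularLDError(
            f"LD matrix singular after regularization (min eigenvalue {w.min():.3e})"
        )
    Rinv = np.linalg.inv(R)
    beta = Rinv @ marg.beta_star
    Omega = R * np.outer(marg.se_star, marg.se_star)
    Sigma = Rinv @ Omega @ Rinv
    return ConditionalGWAS(beta=beta, Sigma=Sigma, n=marg.n, snp_ids=list(marg.snp_ids))


def conditional_to_marginal(cond: ConditionalGWAS, ld: LDMatrix) -> np.ndarray:
    """Invert :func:`marginal_to_conditional` for the point estimates: ``R @ beta``."""
    if ld.m != cond.m:
        raise DimensionMismatchError("dimension mismatch between LD and estimates")
    return ld.R @ cond.beta


def _alleles_match(a1x, a2x, a1y, a2y):
    """Classify allele pairs: 'same', 'flip' (A1/A2 swapped) or None."""
    if (a1x, a2x) == (a1y, a2y):
        return "same"
    if (a1x, a2x) == (a2y, a1y):
        return "flip"
    return None


def harmonize(
    exposure: MarginalGWAS,
    outcome: MarginalGWAS,
    ld: LDMatrix,
    drop_palindromic: bool = False,
):
    """Align exposure, outcome and LD panel on a shared, ordered SNP set.

    The intersection is taken in exposure-file order. Outcome effects are
    sign-flipped where its A1/A2 are swapped relative to the exposure; SNPs
    with irreconcilable alleles are dropped (count logged). Strand-ambiguous
    (A/T, C/G) SNPs are kept by default with a warning; pass
    ``drop_palindromic=True`` to remove them.

    Returns
    -------
    (exposure, outcome, ld) : aligned triple
    """
    out_pos = {s: i for i, s in enumerate(outcome.snp_ids)}
    ld_pos = {s: i for i, s in enumerate(ld.snp_ids)}
    keep_x, keep_y, keep_l, flip = [], [], [], []
    n_allele_drop = n_palindromic = 0
    have_alleles = exposure.a1 is not None and outcome.a1 is not None
    for i, snp in enumerate(exposure.snp_ids):
        if snp not in out_pos or snp not in ld_pos:
            continue
        j = out_pos[snp]
        sign = 1.0
        if have_alleles:
            status = _alleles_match(
                exposure.a1[i], exposure.a2[i], outcome.a1[j], outcome.a2[j]
            )
            if status is None:
                n_allele_drop += 1
                continue
            if status == "flip":
                sign = -1.0
            if (exposure.a1[i], exposure.a2[i]) in _PALINDROMIC:
                n_palindromic += 1
                if drop_palindromic:
                    continue
        keep_x.append(i)
        keep_y.append(j)
        keep_l.append(ld_pos[snp])
        flip.append(sign)
    if not keep_x:
        raise NoCommonSNPsError("no SNP shared by exposure, outcome and LD panel")
    if n_allele_drop:
        logger.info("harmonize: dropped %d SNPs with irreconcilable alleles", n_allele_drop)
    if n_palindromic and not drop_palindromic:
        warnings.warn(
            f"{n_palindromic} strand-ambiguous (A/T or C/G) SNPs kept; "
            "pass drop_palindromic=True to remove them",
            stacklevel=2,
        )
    expo = exposure.subset(keep_x)
    outc = outcome.subset(keep_y)
    flip = np.asarray(flip)
    if np.any(flip < 0):
        outc = replace(
            outc,
            beta_star=outc.beta_star * flip,
            a1=list(expo.a1) if expo.a1 is not None else None,
            a2=list(expo.a2) if expo.a2 is not None else None,
            freq=(1.0 - outc.freq) * (flip < 0) + outc.freq * (flip > 0)
            if outc.freq is not None
            else None,
        )
    return expo, outc, ld.subset(keep_l)
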