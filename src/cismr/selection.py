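"""Instrument selection from summary statistics.

Two strategies are provided. :func:`stepwise_joint_selection` is a
summary-statistic stepwise conditional/joint association search in the style
of GCTA-COJO: SNPs enter when conditionally significant given the current
model, subject to a collinearity cap, and leave when their joint p-value
rises above the threshold. Conditional statistics are computed by joint
generalized least squares on the relevant submatrix of the reference LD
matrix, assuming the panel LD equals the GWAS LD; the effective-sample-size
and allele-frequency bookkeeping of the genotype-based original is not
reproduced, so results are an approximation to it. :func:`ld_clump` is
greedy p-value clumping for independent-instrument baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import NoIVError
from .summary_data import LDMatrix, MarginalGWAS, marginal_to_conditional

DEFAULT_P_THRESHOLD = 5e-6
DEFAULT_COLLINEAR = 0.9


@dataclass
class SelectionResult:
    """Outcome of a stepwise conditional/joint selection run."""

    selected: list
    joint_beta: np.ndarray
    joint_se: np.ndarray
    p_threshold: float
    collinear_limit: float
    joint_p: np.ndarray = field(default=None)

    @property
    def k(self) -> int:
        return len(self.selected)


def _joint_fit(marg: MarginalGWAS, ld: LDMatrix, idx):
    """Joint conditional estimates and per-SNP z / p for the SNP set ``idx``."""
    cond = marginal_to_conditional(marg.subset(idx), ld.subset(idx))
    se = np.sqrt(np.diag(cond.Sigma))
    z = cond.beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return cond.beta, se, p


def stepwise_joint_selection(
    marg: MarginalGWAS,
    ld: LDMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    collinear_limit: float = DEFAULT_COLLINEAR,
) -> SelectionResult:
    """Forward-backward stepwise selection of jointly associated SNPs.

    Starts from the smallest marginal p-value if below ``p_threshold``; at
    each step every unselected SNP whose absolute correlation with the current
    model stays below ``collinear_limit`` is scored by its conditional z in
    the candidate-augmented joint fit, and the best one enters if its
    conditional p is below the threshold. After every addition the joint
    model is refit and SNPs whose joint p exceeds the threshold are dropped.
    An empty selection is a valid result.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    m = marg.m
    z_marg = marg.beta_star / marg.se_star
    p_marg = 2 * stats.norm.sf(np.abs(z_marg))
    order0 = int(np.argmin(p_marg))
    if p_marg[order0] >= p_threshold:
        return SelectionResult([], np.empty(0), np.empty(0), p_threshold,
                               collinear_limit, np.empty(0))
    selected = [order0]
    R = ld.R
    for _ in range(3 * m):
        # forward step: best conditionally significant, non-collinear candidate
        best_j, best_p = None, p_threshold
        for j in range(m):
            if j in selected:
                continue
            if np.max(np.abs(R[j, selected])) >= collinear_limit:
                continue
            trial = selected + [j]
            _, _, p_joint = _joint_fit(marg, ld, trial)
            pj = p_joint[-1]
            if pj < best_p:
                best_j, best_p = j, pj
        changed = False
        if best_j is not None:
            selected.append(best_j)
            changed = True
        # backward step: drop SNPs no longer jointly significant
        while len(selected) > 1:
            _, _, p_joint = _joint_fit(marg, ld, selected)
            worst = int(np.argmax(p_joint))
            if p_joint[worst] < p_threshold:
                break
            selected.pop(worst)
            changed = True
        if not changed:
            break
    if len(selected) == 1:
        # single-SNP joint model equals the marginal one
        _, _, p_joint = _joint_fit(marg, ld, selected)
        if p_joint[0] >= p_threshold:
            selected = []
    if not selected:
        return SelectionResult([], np.empty(0), np.empty(0), p_threshold,
                               collinear_limit, np.empty(0))
    beta, se, p_joint = _joint_fit(marg, ld, selected)
    return SelectionResult(
        selected=list(selected),
        joint_beta=beta,
        joint_se=se,
        p_threshold=p_threshold,
        collinear_limit=collinear_limit,
        joint_p=p_joint,
    )


def build_candidate_set(sel_x: SelectionResult, sel_y: SelectionResult):
    """Union of exposure- and outcome-selected SNPs, in panel (exposure-file) order.

    Returns
    -------
    (indices, labels) : sorted index list and a matching list of
        ``"X-only"`` / ``"Y-only"`` / ``"both"`` annotations.
    """
    sx, sy = set(sel_x.selected), set(sel_y.selected)
    union = sorted(sx | sy)
    if not union:
        raise NoIVError("no SNP selected for either trait")
    labels = [
        "both" if i in sx and i in sy else ("X-only" if i in sx else "Y-only")
        for i in union
    ]
    return union, labels


def ld_clump(
    marg: MarginalGWAS, ld: LDMatrix, r2_threshold: float = 0.001
):
    """Greedy LD clumping: keep the best remaining SNP, discard its r^2 neighbours."""
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must lie in (0, 1]")
    if marg.p is not None:
        p = np.asarray(marg.p, dtype=float)
    else:
        p = 2 * stats.norm.sf(np.abs(marg.beta_star / marg.se_star))
    r2 = ld.R**2
    remaining = list(np.lexsort((np.arange(marg.m), p)))
    kept = []
    while remaining:
        top = remaining.pop(0)
        kept.append(top)
        remaining = [j for j in remaining if r2[top, j] < r2_threshold]
    return sorted(kept)
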