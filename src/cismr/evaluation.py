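"""Replicate-level benchmarking and the summary metrics used to compare methods.

The harness repeatedly simulates summary statistics, fits a set of
estimators, and tabulates rejection rates (type-I error under the null,
power under an alternative), bias and RMSE of the causal estimate.
Also provided: mean per-SNP marginal F-statistic (instrument strength),
the genomic inflation factor lambda, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import cml, estimators
from .selection import build_candidate_set, stepwise_joint_selection
from .summary_data import MarginalGWAS, marginal_to_conditional, standardize_marginal
from .simulate import (
    IndividualSimConfig,
    SummarySimConfig,
    gwas_scan,
    ld_from_genotypes,
    simulate_individual,
    simulate_summary,
)
from .errors import CisMRError, NoIVError

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...


def mean_f_statistic(marg) -> float:
    """Mean over SNPs of the marginal Wald chi-square ``(beta*/se*)^2``."""
    if np.any(marg.se_star == 0):
        raise ZeroDivisionError("zero standard error in F-statistic")
    return float(np.mean((marg.beta_star / marg.se_star) ** 2))


def inflation_factor(pvals) -> float:
    """Genomic inflation lambda: median implied chi-square over the null median."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns the monotonized adjusted p-values and a boolean reject vector
    (adjusted p < q).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


# ---------------------------------------------------------------------------
# method dispatch for the replicate harness
# ---------------------------------------------------------------------------


def _theta_p(est) -> tuple:
    return est.theta, est.p


def _restrict(rep, idx):
    idx = list(idx)
    expo = rep["exposure"].subset(idx)
    outc = rep["outcome"].subset(idx)
    ld = rep["ld"].subset(idx)
    return expo, outc, ld


def _x_indices(rep):
    if "x_idx" in rep:
        return rep["x_idx"]
    return rep["cfg"].i_x


def _fit_method(name, rep, alpha, rng):
    expo, outc, ld = rep["exposure"], rep["outcome"], rep["ld"]
    cfg = rep["cfg"]
    if name.endswith("_x"):
        expo, outc, ld = _restrict(rep, _x_indices(rep))
        name = name[:-2]
    if name == "givw":
        return _theta_p(estimators.givw(expo, outc, ld))
    if name == "gegger":
        return _theta_p(estimators.gegger(expo, outc, ld))
    if name in ("livw", "legger", "cml_bic", "cml_dp", "cml"):
        cx = marginal_to_conditional(expo, ld)
        cy = marginal_to_conditional(outc, ld)
        if name == "livw":
            return _theta_p(estimators.livw(cx, cy))
        if name == "legger":
            return _theta_p(estimators.legger(cx, cy))
        if name == "cml_bic":
            res = cml.bic_scan(cx, cy, expo.n, outc.n,
                               rng=np.random.default_rng(rng.integers(2**31)))
            return res.theta, res.p
        dp = cml.data_perturbation(cx, cy, expo.n, outc.n,
                                   seed=int(rng.integers(2**31)))
        return dp.theta, dp.p
    if name == "cml_marg":
        res = cml.fit_marginal_model(expo, outc, ld,
                                     rng=np.random.default_rng(rng.integers(2**31)))
        return res.theta, res.p
    if name == "wald":
        j = int(np.argmax(np.abs(expo.beta_star / expo.se_star)))
        return _theta_p(estimators.wald_ratio(expo.subset([j]), outc.subset([j])))
    raise ValueError(f"unknown method {name!r}")


def _standardized_gwas(G, phen, n):
    gw, _ = gwas_scan(G, phen)
    beta, se = standardize_marginal(gw.beta_star, gw.se_star, n)
    return MarginalGWAS(gw.snp_ids, beta, se, n)


def _individual_replicate(cfg: IndividualSimConfig, rng, p_threshold=5e-6):
    """One individual-level replicate: GWAS scans, selection, union panel."""
    out = simulate_individual(cfg, rng=rng)
    expo = _standardized_gwas(out["G_x"], out["X"], cfg.n_x)
    outc = _standardized_gwas(out["G_y"], out["Y"], cfg.n_y)
    if expo.m != cfg.m or outc.m != cfg.m:
        raise NoIVError("monomorphic SNPs in a GWAS cohort")
    ld = ld_from_genotypes(out["G_ref"], snp_ids=expo.snp_ids)
    sel_x = stepwise_joint_selection(expo, ld, p_threshold=p_threshold)
    sel_y = stepwise_joint_selection(outc, ld, p_threshold=p_threshold)
    union, _labels = build_candidate_set(sel_x, sel_y)
    pos = {i: j for j, i in enumerate(union)}
    return {
        "exposure": expo.subset(union),
        "outcome": outc.subset(union),
        "ld": ld.subset(union),
        "x_idx": [pos[i] for i in sorted(sel_x.selected)],
        "truth": out["truth"],
        "cfg": cfg,
    }


def run_replicates(
    cfg,
    methods,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Simulate ``n_reps`` replicates of ``cfg`` and benchmark each method.

    ``cfg`` is either a :class:`SummarySimConfig` (summary statistics drawn
    directly) or an :class:`IndividualSimConfig` (genotype cohorts, per-SNP
    GWAS scans, stepwise selection on both traits and the union instrument
    panel, mirroring the applied pipeline). ``methods`` is a list of method
    names (``givw``, ``gegger``, ``livw``, ``legger``, ``cml_bic``,
    ``cml_dp``, ``cml_marg``, ``wald``; a ``_x`` suffix restricts the
    analysis to the exposure-associated SNPs — ``cfg.i_x`` for the summary
    design, the exposure-selected set for the individual design) and/or
    ``(label, callable)`` pairs where the callable maps a replicate dict
    (keys exposure, outcome, ld, truth, cfg) to ``(theta, p)``. Failed fits
    are excluded and counted.

    Returns a DataFrame indexed by method with the rejection rate at level
    ``alpha``, bias and RMSE of the causal estimate against ``cfg.theta``,
    and failure counts: the rejection rate is the empirical type-I error when
    ``cfg.theta == 0`` and the power otherwise.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    named = []
    for mth in methods:
        if isinstance(mth, str):
            named.append((mth, None))
        else:
            named.append((mth[0], mth[1]))
    records = {label: [] for label, _ in named}
    fails = {label: 0 for label, _ in named}
    individual = isinstance(cfg, IndividualSimConfig)
    for k in range(n_reps):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, k])
        if individual:
            try:
                rep = _individual_replicate(cfg, rng)
            except (CisMRError, np.linalg.LinAlgError):
                for label, _ in named:
                    fails[label] += 1
                continue
        else:
            expo, outc, ld, truth = simulate_summary(cfg, rng=rng)
            rep = {"exposure": expo, "outcome": outc, "ld": ld,
                   "truth": truth, "cfg": cfg}
        for label, fn in named:
            try:
                if fn is None:
                    theta, p = _fit_method(label, rep, alpha, rng)
                else:
                    theta, p = fn(rep)
            except Exception:
                fails[label] += 1
                continue
            records[label].append((theta, p))
    rows = []
    for label, _ in named:
        arr = np.asarray(records[label], dtype=float).reshape(-1, 2)
        err = arr[:, 0] - cfg.theta
        rows.append(
            {
                "method": label,
                "n_reps": arr.shape[0],
                "n_fail": fails[label],
                "reject_rate": float(np.mean(arr[:, 1] < alpha)) if arr.size else np.nan,
                "bias": float(err.mean()) if arr.size else np.nan,
                "rmse": float(np.sqrt(np.mean(err**2))) if arr.size else np.nan,
                "mean_theta": float(arr[:, 0].mean()) if arr.size else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("method")


def benchmark_scenario(
    cfg: SummarySimConfig,
    methods,
    n_reps: int,
    theta_alt: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Null and alternative runs merged into one table (type1, power, RMSE, bias).

    The null uses ``cfg`` with ``theta = 0``; the alternative sets
    ``theta = theta_alt``. RMSE and bias are reported under the null.
    """
    null_cfg = replace(cfg, theta=0.0)
    alt_cfg = replace(cfg, theta=theta_alt)
    t0 = run_replicates(null_cfg, methods, n_reps, alpha=alpha, seed=seed)
    t1 = run_replicates(alt_cfg, methods, n_reps, alpha=alpha, seed=seed + 1)
    out = pd.DataFrame(
        {
            "type1": t0["reject_rate"],
            "power": t1["reject_rate"],
            "rmse": t0["rmse"],
            "bias": t0["bias"],
            "n_reps": t0["n_reps"],
            "n_fail": t0["n_fail"] + t1["n_fail"],
        }
    )
    return out
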