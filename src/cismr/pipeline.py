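"""End-to-end analysis: harmonize, select instruments, transform, fit.

The pipeline mirrors the intended applied workflow for a cis-region:

1. read exposure/outcome ``.ma`` files and the LD matrix, harmonize alleles;
2. stepwise conditional/joint selection on the exposure and on the outcome;
3. form the union candidate set (exposure- or outcome-associated SNPs);
4. transform marginal statistics on the union set to conditional estimates;
5. fit the requested estimators — the constrained-ML method on the
   conditional union-set estimates, the generalized IVW/Egger comparators
   optionally restricted to the exposure-selected set (the ``-X`` variants);
6. write a results TSV plus a JSON manifest holding every threshold and seed
   so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cml, estimators, io, selection
from .errors import NoIVError
from .summary_data import harmonize, marginal_to_conditional

logger = logging.getLogger(__name__)

KNOWN_METHODS = (
    "cml", "cml_bic", "givw", "gegger", "livw", "legger", "wald",
    "givw_x", "gegger_x", "cml_x", "legger_x",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all thresholds and seeds explicit)."""

    exposure: str
    outcome: str
    ld: str
    methods: tuple = ("cml", "givw_x", "gegger_x", "legger")
    p_threshold: float = selection.DEFAULT_P_THRESHOLD
    collinear_limit: float = selection.DEFAULT_COLLINEAR
    r2_clump: float = 0.001
    k_set: tuple | None = None
    n_starts: int = cml.DEFAULT_N_STARTS
    start_width: float = cml.DEFAULT_START_WIDTH
    dp: bool = True
    B: int = cml.DEFAULT_B
    seed: int = 0
    out_prefix: str = "cismr_run"

    def __post_init__(self):
        if not self.methods:
            raise ValueError("at least one method must be requested")
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValueError(f"unknown method(s): {unknown}")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")


def _estimate_row(est, extra=None):
    row = {
        "method": est.method,
        "m": est.m_used,
        "theta": est.theta,
        "se": est.se,
        "p": est.p,
        "intercept": est.intercept,
        "intercept_se": est.intercept_se,
    }
    row.update(extra or {})
    return row


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline; returns the results table and writes outputs."""
    expo = io.read_gwas_table(cfg.exposure)
    outc = io.read_gwas_table(cfg.outcome)
    ld = io.read_ld_matrix(cfg.ld)
    expo, outc, ld = harmonize(expo, outc, ld)
    logger.info("pipeline: %d SNPs after harmonization", expo.m)

    sel_x = selection.stepwise_joint_selection(
        expo, ld, cfg.p_threshold, cfg.collinear_limit
    )
    sel_y = selection.stepwise_joint_selection(
        outc, ld, cfg.p_threshold, cfg.collinear_limit
    )
    try:
        union, labels = selection.build_candidate_set(sel_x, sel_y)
    except NoIVError:
        raise NoIVError(
            "stepwise selection found no exposure- or outcome-associated SNP "
            f"at p < {cfg.p_threshold:g}"
        )
    logger.info(
        "pipeline: selected |C_X|=%d |C_Y|=%d union=%d", sel_x.k, sel_y.k, len(union)
    )

    expo_u, outc_u, ld_u = expo.subset(union), outc.subset(union), ld.subset(union)
    cond_x = marginal_to_conditional(expo_u, ld_u)
    cond_y = marginal_to_conditional(outc_u, ld_u)
    x_only = sorted(sel_x.selected)

    rows = []
    cml_extra = {}
    for method in cfg.methods:
        if method in ("givw_x", "gegger_x", "cml_x", "legger_x") and x_only:
            ex, oy, lx = expo.subset(x_only), outc.subset(x_only), ld.subset(x_only)
        else:
            ex, oy, lx = expo_u, outc_u, ld_u
        if method == "givw":
            rows.append(_estimate_row(estimators.givw(ex, oy, lx)))
        elif method == "givw_x":
            est = estimators.givw(ex, oy, lx)
            est.method = "givw_x"
            rows.append(_estimate_row(est))
        elif method == "gegger":
            rows.append(_estimate_row(estimators.gegger(ex, oy, lx)))
        elif method == "gegger_x":
            est = estimators.gegger(ex, oy, lx)
            est.method = "gegger_x"
            rows.append(_estimate_row(est))
        elif method == "livw":
            rows.append(_estimate_row(estimators.livw(cond_x, cond_y)))
        elif method == "legger":
            rows.append(_estimate_row(estimators.legger(cond_x, cond_y)))
        elif method == "legger_x":
            cx = marginal_to_conditional(ex, lx)
            cy = marginal_to_conditional(oy, lx)
            est = estimators.legger(cx, cy)
            est.method = "legger_x"
            rows.append(_estimate_row(est))
        elif method == "wald":
            j = int(np.argmax(np.abs(expo.beta_star / expo.se_star)))
            rows.append(
                _estimate_row(estimators.wald_ratio(expo.subset([j]), outc.subset([j])))
            )
        elif method in ("cml", "cml_bic", "cml_x"):
            if method == "cml_x":
                cx = marginal_to_conditional(ex, lx)
                cy = marginal_to_conditional(oy, lx)
                ids = ex.snp_ids
            else:
                cx, cy = cond_x, cond_y
                ids = expo_u.snp_ids
            res = cml.bic_scan(
                cx, cy, ex.n, oy.n, k_set=cfg.k_set, n_starts=cfg.n_starts,
                start_width=cfg.start_width, seed=cfg.seed,
            )
            invalid_ids = [ids[i] for i in res.invalid_set]
            extra = {"k_hat": res.k_hat, "invalid_snps": ",".join(invalid_ids)}
            if cfg.dp and method != "cml_bic":
                dp = cml.data_perturbation(
                    cx, cy, ex.n, oy.n, B=cfg.B, seed=cfg.seed,
                    k_set=cfg.k_set, n_starts=cfg.n_starts,
                    start_width=cfg.start_width,
                )
                rows.append(
                    {
                        "method": method + "_dp",
                        "m": cx.m,
                        "theta": dp.theta,
                        "se": dp.se,
                        "p": dp.p,
                        "intercept": None,
                        "intercept_se": None,
                        **extra,
                    }
                )
                cml_extra["invalid_frequency"] = {
                    ids[i]: float(f) for i, f in enumerate(dp.invalid_frequency)
                }
            else:
                rows.append(
                    {
                        "method": method + "_bic",
                        "m": cx.m,
                        "theta": res.theta,
                        "se": res.se,
                        "p": res.p,
                        "intercept": None,
                        "intercept_se": None,
                        **extra,
                    }
                )
    table = pd.DataFrame(rows)

    out = Path(cfg.out_prefix)
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(f"{out}.tsv", sep="\t", index=False, float_format="%.6g")
    manifest = {
        "config": asdict(cfg),
        "n_snps_harmonized": expo.m,
        "selected_x": [expo.snp_ids[i] for i in sel_x.selected],
        "selected_y": [expo.snp_ids[i] for i in sel_y.selected],
        "union": [expo.snp_ids[i] for i in union],
        "union_labels": labels,
        "results": table.to_dict(orient="records"),
        **cml_extra,
    }
    io.write_json(manifest, f"{out}.manifest.json")
    return table
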