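"""Readers and writers for summary-statistic files and LD matrices.

Summary files follow the GCTA-COJO ``.ma`` dialect: whitespace/tab-delimited
with header ``SNP A1 A2 freq b se p N`` (``freq`` and ``p`` optional).
LD matrices are square numeric text, optionally with a leading SNP-id column.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .summary_data import LDMatrix, MarginalGWAS

logger = logging.getLogger(__name__)

_REQUIRED = ("SNP", "A1", "A2", "b", "se", "N")
_KNOWN = set(_REQUIRED) | {"freq", "p"}


def read_gwas_table(path) -> MarginalGWAS:
    """Parse a ``.ma`` summary file into a validated :class:`MarginalGWAS`.

    Per-SNP sample sizes are permitted and collapsed to their minimum for the
    region. Unknown extra columns are ignored with a logged note.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    extras = [c for c in df.columns if c not in _KNOWN]
    if extras:
        logger.info("%s: ignoring extra columns %s", path, extras)
    for col in ("b", "se", "N"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col])
    return MarginalGWAS(
        snp_ids=df["SNP"].astype(str).tolist(),
        beta_star=df["b"].to_numpy(float),
        se_star=df["se"].to_numpy(float),
        n=int(df["N"].min()),
        a1=df["A1"].astype(str).tolist(),
        a2=df["A2"].astype(str).tolist(),
        freq=df["freq"].to_numpy(float) if "freq" in df.columns else None,
        p=df["p"].to_numpy(float) if "p" in df.columns else None,
    )


def write_gwas_table(marg: MarginalGWAS, path) -> None:
    cols = {
        "SNP": marg.snp_ids,
        "A1": marg.a1 if marg.a1 is not None else ["A"] * marg.m,
        "A2": marg.a2 if marg.a2 is not None else ["G"] * marg.m,
    }
    if marg.freq is not None:
        cols["freq"] = marg.freq
    cols["b"] = marg.beta_star
    cols["se"] = marg.se_star
    cols["p"] = (
        marg.p
        if marg.p is not None
        else 2 * _norm_sf(np.abs(marg.beta_star / marg.se_star))
    )
    cols["N"] = marg.n
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _norm_sf(z):
    from scipy import stats

    return stats.norm.sf(z)


def read_ld_matrix(path, snp_ids=None) -> LDMatrix:
    """Read a square LD matrix, with or without a leading SNP-id column."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().split()
    if not first:
        raise ValueError(f"{path}: empty LD file")
    try:
        float(first[0])
        has_ids = False
    except ValueError:
        has_ids = True
    if has_ids:
        df = pd.read_csv(path, sep=r"\s+", header=None, index_col=0)
        ids = [str(s) for s in df.index]
        R = df.to_numpy(float)
    else:
        R = np.loadtxt(path)
        R = np.atleast_2d(R)
        ids = snp_ids if snp_ids is not None else [f"snp{i+1}" for i in range(R.shape[0])]
    if snp_ids is not None and has_ids:
        pos = {s: i for i, s in enumerate(ids)}
        missing = [s for s in snp_ids if s not in pos]
        if missing:
            raise ValueError(f"{path}: LD matrix lacks SNPs {missing[:5]}")
        order = [pos[s] for s in snp_ids]
        R = R[np.ix_(order, order)]
        ids = list(snp_ids)
    return LDMatrix(R, ids)


def write_ld_matrix(ld: LDMatrix, path, with_ids: bool = True) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(ld.R):
            vals = " ".join(f"{v:.10g}" for v in row)
            fh.write((f"{ld.snp_ids[i]} " if with_ids else "") + vals + "\n")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
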