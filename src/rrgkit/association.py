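"""Correlation of per-cell %RRG with candidate regulator gene expression.

Receptor and transcriptional co-regulator transcripts (Pgr, Esr1, Ncoa1,
Ncor1, Ncor2, ...) are correlated against the per-cell hormone-response
magnitude.  Spearman (mid-rank ties, t-approximation p) and Pearson (t with
n-2 df) are both reported; expression is the log-normalized value including
zeros.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .degs import bh_adjust
from .rrg import RRGResult

__all__ = ["rank_correlation", "pearson_correlation", "associate_rrg"]


def _validate(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    return x, y


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rho (mid-rank ties) and its t-approximation p-value.

    A constant input has no rank ordering; (nan, nan) is returned with a
    warning.
    """
    x, y = _validate(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r and its t-distribution p-value (n-2 df)."""
    x, y = _validate(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("zero-variance vector: Pearson correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def associate_rrg(
    norm: ad.AnnData,
    rrg: RRGResult,
    candidate_genes: list[str],
    cell_mask=None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Correlate each candidate gene's expression with per-cell %RRG.

    The default cell subset is hormone-treated ERalpha+ cells (any condition
    other than ``vehicle``); pass ``cell_mask`` to override.  Constant
    candidates yield missing correlations with a warning.  ``adjust`` adds BH
    columns across the candidate panel (off by default: small panels are
    conventionally reported raw).
    """
    if cell_mask is None:
        obs = norm.obs
        cell_mask = ((obs["condition"] != "vehicle") & (obs["population"] == "ERpos")).to_numpy()
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty cell subset")
    missing = [g for g in candidate_genes if g not in norm.var_names]
    if missing:
        raise KeyError(f"candidate genes not in the matrix: {missing}")

    cells = norm.obs_names[mask]
    y = rrg.cells.loc[cells, "pct_rrg"].to_numpy()
    rows = []
    for gene in candidate_genes:
        col = norm[mask, gene].X
        x = (col.toarray() if sp.issparse(col) else np.asarray(col)).ravel()
        if np.all(x == x[0]) or np.all(y == y[0]):
            warnings.warn(f"candidate {gene!r}: constant input, correlation undefined", stacklevel=2)
            rho = rho_p = r = r_p = float("nan")
        else:
            rho, rho_p = rank_correlation(x, y)
            r, r_p = pearson_correlation(x, y)
        rows.append({"gene": gene, "spearman_rho": rho, "spearman_p": rho_p,
                     "pearson_r": r, "pearson_p": r_p, "n_cells": int(mask.sum())})
    out = pd.DataFrame(rows).set_index("gene")
    if adjust:
        for col_p in ("spearman_p", "pearson_p"):
            ok = out[col_p].notna()
            adj = np.full(len(out), np.nan)
            if ok.any():
                adj[ok.to_numpy()] = bh_adjust(out.loc[ok, col_p].to_numpy())
            out[col_p.replace("_p", "_padj")] = adj
    return out
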