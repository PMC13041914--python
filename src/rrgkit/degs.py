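"""Single-cell differential expression: per-gene Wilcoxon rank-sum tests,
fold-change estimation on the de-logged normalized scale, BH-FDR adjustment,
and threshold gating into DEG selections.

The conventions mirror the widely used single-cell workflow: two-sided
Mann-Whitney U with mid-rank tie correction and continuity correction, fold
changes computed as ``log2((mean(expm1 x_a) + pc) / (mean(expm1 x_b) + pc))``
with pseudocount ``pc = 1``, BH adjustment over all genes tested in the
contrast, and the upregulated-DEG gate ``padj < padj_max`` (strict) and
``|log2FC| >= min_abs_log2fc`` (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEGSelection",
    "wilcoxon_gene_test",
    "log2fc",
    "bh_adjust",
    "select_degs",
    "run_de",
]


@dataclass
class DEGSelection:
    """An upregulated/downregulated DEG gene set with the thresholds that produced it."""

    genes: list[str]
    padj_max: float
    min_abs_log2fc: float
    direction: str


def _group_matrices(norm: ad.AnnData, mask_a, mask_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both cell groups must be non-empty")
    if (a & b).any():
        raise ValueError("cell groups overlap")
    X = norm.X
    Xa = (X[a].toarray() if sp.issparse(X) else np.asarray(X[a])).T  # genes x n_a
    Xb = (X[b].toarray() if sp.issparse(X) else np.asarray(X[b])).T
    return Xa, Xb


def wilcoxon_gene_test(norm: ad.AnnData, mask_a, mask_b) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value per gene (group a vs group b).

    Uses the tie-corrected normal approximation with continuity correction.
    Genes whose values are identical across both groups carry no signal and
    get p = 1.
    """
    Xa, Xb = _group_matrices(norm, mask_a, mask_b)
    constant = (Xa.min(axis=1) == Xa.max(axis=1)) & (Xb.min(axis=1) == Xb.max(axis=1)) & (
        Xa[:, 0] == Xb[:, 0]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            Xa, Xb, axis=-1, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = np.asarray(res.pvalue, dtype=float)
    p[constant] = 1.0
    p[np.isnan(p)] = 1.0  # degenerate all-tie slices where the variance vanishes
    return np.minimum(p, 1.0)


def log2fc(norm: ad.AnnData, mask_a, mask_b, pseudocount: float = 1.0) -> np.ndarray:
    """Per-gene log2 fold change of group a over group b.

    Computed on the de-logged normalized scale:
    ``log2((mean(expm1 x_a) + pc) / (mean(expm1 x_b) + pc))``.
    """
    Xa, Xb = _group_matrices(norm, mask_a, mask_b)
    ma = np.expm1(Xa).mean(axis=1)
    mb = np.expm1(Xb).mean(axis=1)
    return np.log2((ma + pseudocount) / (mb + pseudocount))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(
    table: pd.DataFrame,
    padj_max: float = 0.05,
    min_abs_log2fc: float = 0.25,
    direction: str = "up",
) -> DEGSelection:
    """Gate a DEG table into a gene selection.

    Keeps genes with ``padj < padj_max`` (strict) and
    ``|log2FC| >= min_abs_log2fc`` (inclusive), filtered by direction
    (``up``: positive log2FC only -- the %RRG convention; ``down``; ``both``).
    """
    if padj_max <= 0 or min_abs_log2fc < 0:
        raise ValueError("thresholds must be positive")
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    keep = (table["padj"] < padj_max) & (table["log2fc"].abs() >= min_abs_log2fc)
    if direction == "up":
        keep &= table["log2fc"] > 0
    elif direction == "down":
        keep &= table["log2fc"] < 0
    return DEGSelection(
        genes=list(table.index[keep]),
        padj_max=padj_max,
        min_abs_log2fc=min_abs_log2fc,
        direction=direction,
    )


def run_de(norm: ad.AnnData, mask_a, mask_b, pseudocount: float = 1.0) -> pd.DataFrame:
    """Full treated-vs-vehicle DEG table for one contrast.

    Columns: ``log2fc`` (a over b), ``pval``, ``padj`` (BH over all genes
    tested), per-group means on the normalized scale, per-group nonzero
    fractions, and the direction flag consistent with the log2FC sign.
    """
    Xa, Xb = _group_matrices(norm, mask_a, mask_b)
    pvals = wilcoxon_gene_test(norm, mask_a, mask_b)
    lfc = log2fc(norm, mask_a, mask_b, pseudocount)
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "pval": pvals,
            "padj": bh_adjust(pvals),
            "mean_a": Xa.mean(axis=1),
            "mean_b": Xb.mean(axis=1),
            "pct_a": (Xa > 0).mean(axis=1),
            "pct_b": (Xb > 0).mean(axis=1),
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "flat")),
        },
        index=norm.var_names.copy(),
    )
    return table
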