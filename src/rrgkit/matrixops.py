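"""Count-matrix operations: mito QC, log-normalization, depth downsampling,
gene-positive fractions.

All functions take an AnnData in the cells-by-genes orientation with integer
UMI counts in ``X`` (sparse or dense) and return new objects; inputs are never
modified in place.
"""

from __future__ import annotations

import logging
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "qc_filter_mito",
    "lognormalize",
    "downsample_to_depth",
    "positive_fraction",
]


def _counts_matrix(adata: ad.AnnData) -> sp.csr_matrix:
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    return X.tocsr()


def qc_filter_mito(
    adata: ad.AnnData,
    max_mito_pct: float = 10.0,
    *,
    mito_flag_col: str = "mito",
    symbol_prefix: str | None = "mt-",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove cells whose mitochondrial UMI percentage strictly exceeds the cutoff.

    Mito genes are taken from the boolean ``var[mito_flag_col]`` when present,
    otherwise flagged by the (case-insensitive) ``symbol_prefix`` on gene
    symbols -- the mouse ``mt-`` convention by default.  A rule that flags no
    genes keeps every cell and logs a warning; having neither a flag column
    nor a prefix rule is an error, because a silent no-op filter would be
    indistinguishable from real QC.

    Returns the filtered matrix and a report of removed barcodes with their
    mito percentages.
    """
    if mito_flag_col in adata.var:
        flags = adata.var[mito_flag_col].to_numpy(dtype=bool)
    elif symbol_prefix is not None:
        flags = np.asarray(adata.var_names.str.lower().str.startswith(symbol_prefix.lower()))
    else:
        raise ValueError(
            "no mito flag column and no symbol prefix rule supplied; "
            "cannot apply the mitochondrial QC filter"
        )
    if not flags.any():
        logger.warning("mito rule flags no genes; all %d cells retained", adata.n_obs)
        return adata.copy(), pd.DataFrame(columns=["barcode", "mito_pct"]).set_index("barcode")

    X = _counts_matrix(adata)
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_totals = np.asarray(X[:, flags].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * mito_totals / totals, 0.0)
    keep = pct <= max_mito_pct  # strict ">" removal
    report = pd.DataFrame(
        {"mito_pct": pct[~keep]}, index=pd.Index(adata.obs_names[~keep], name="barcode")
    )
    return adata[keep].copy(), report


def lognormalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Depth-normalize and log-transform: x = ln(1 + count * scale_factor / cell_total).

    Zeros map exactly to zero, so sparsity is preserved.  Cells with zero
    total UMIs cannot be normalized and raise an error naming the barcode.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    X = _counts_matrix(adata).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = adata.obs_names[np.flatnonzero(totals <= 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total UMIs; remove it before normalizing")
    out = X.multiply(scale_factor / totals[:, None]).tocsr()
    out.data = np.log1p(out.data)
    norm = ad.AnnData(X=out, obs=adata.obs.copy(), var=adata.var.copy())
    norm.uns["lognorm"] = {"scale_factor": float(scale_factor), "log_base": "e"}
    return norm


def downsample_to_depth(
    adata: ad.AnnData,
    target_mean: float | None = None,
    reference: ad.AnnData | None = None,
    seed: int = 0,
) -> ad.AnnData:
    """Binomially thin counts so the mean per-cell UMI depth matches a target.

    The target is either given directly or taken from a reference dataset's
    mean depth (depth matching between datasets).  Every entry is thinned
    independently with retention probability ``p = target_mean / source_mean``;
    each output entry is bounded by its input entry.  Upsampling is undefined.
    """
    if (target_mean is None) == (reference is None):
        raise ValueError("supply exactly one of target_mean or reference")
    if reference is not None:
        target_mean = float(np.asarray(_counts_matrix(reference).sum(axis=1)).mean())
    assert target_mean is not None
    X = _counts_matrix(adata)
    source_mean = float(np.asarray(X.sum(axis=1)).mean()) if adata.n_obs else 0.0
    if target_mean > source_mean:
        raise ValueError(
            f"target mean depth {target_mean:.1f} exceeds source mean {source_mean:.1f}; "
            "upsampling is undefined"
        )
    p = target_mean / source_mean if source_mean > 0 else 1.0
    out = X.copy()
    if p < 1.0:
        rng = np.random.default_rng(seed)
        out.data = rng.binomial(out.data.astype(np.int64), p).astype(X.dtype)
        out.eliminate_zeros()
    ds = ad.AnnData(X=out, obs=adata.obs.copy(), var=adata.var.copy())
    ds.uns["downsample"] = {"retention_p": p, "target_mean": float(target_mean), "seed": seed}
    return ds


def positive_fraction(
    adata: ad.AnnData,
    gene: str,
    min_umi: int = 1,
    cell_mask: Sequence[bool] | np.ndarray | None = None,
) -> tuple[float, int]:
    """Fraction (and count) of cells with at least ``min_umi`` UMIs of ``gene``.

    Gene-positive cells are defined by detection of >= 1 UMI by default.
    """
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not present in the gene table")
    mask = np.ones(adata.n_obs, dtype=bool) if cell_mask is None else np.asarray(cell_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty cell subset")
    col = adata[:, gene].X
    counts = (col.toarray() if sp.issparse(col) else np.asarray(col)).ravel()[mask]
    n_pos = int((counts >= min_umi).sum())
    return n_pos / int(mask.sum()), n_pos
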