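"""The per-cell "ratio of responding genes" (%RRG) statistic.

For an upregulated-DEG gene set, baseline expression is summarised per gene
from timepoint-matched vehicle ERalpha+ cells: the mean and standard deviation
of the *nonzero* log-normalized values (zeros are excluded from baseline
estimation only).  A gene "responds" in an evaluated cell when its expression
strictly exceeds the baseline mean plus one standard deviation, and the
cell's %RRG is 100 times the fraction of baseline-defined DEG genes that
respond.  Treated and vehicle %RRG distributions are compared with two-sided
Wilcoxon rank-sum tests, and responder/non-responder bimodality is assessed
with a joint Hartigan-dip + Gaussian-mixture-BIC rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.mixture import GaussianMixture

from ._dip import dip_pvalue
from .degs import DEGSelection

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineStats",
    "RRGResult",
    "CompareResult",
    "BimodalityResult",
    "baseline_mask",
    "baseline_stats",
    "rrg_per_cell",
    "compare_rrg",
    "bimodality",
]


@dataclass
class BaselineStats:
    """Per-gene zero-excluded baseline summaries from vehicle ERalpha+ cells.

    ``stats`` has one row per requested gene: ``mu`` and ``sigma`` are the
    sample mean and sample SD (n-1 denominator) of the nonzero values,
    ``n_nonzero`` the support count, and ``defined`` is False when fewer than
    two nonzero values were available (sigma not estimable; such genes are
    dropped from the %RRG denominator).
    """

    stats: pd.DataFrame
    n_baseline_cells: int

    @property
    def defined_genes(self) -> pd.Index:
        return self.stats.index[self.stats["defined"]]


@dataclass
class RRGResult:
    """Per-cell %RRG values with their group labels.

    ``cells`` columns: ``n_defined`` (constant denominator), ``n_responding``,
    ``pct_rrg`` in [0, 100], plus population/condition/timepoint labels when
    present in the source metadata.
    """

    cells: pd.DataFrame
    deg_set_size: int
    n_defined: int


@dataclass
class CompareResult:
    median_a: float
    median_b: float
    median_ratio: float
    u_statistic: float
    pvalue: float
    n_a: int
    n_b: int


@dataclass
class BimodalityResult:
    dip: float
    dip_pvalue: float
    delta_bic: float
    modes: tuple[float, ...]
    bimodal: bool


def baseline_mask(
    adata: ad.AnnData,
    timepoint: str,
    vehicle_label: str = "vehicle",
    population: str = "ERpos",
) -> np.ndarray:
    """Boolean mask of timepoint-matched vehicle ERalpha+ cells."""
    obs = adata.obs
    return (
        (obs["condition"] == vehicle_label)
        & (obs["timepoint"] == timepoint)
        & (obs["population"] == population)
    ).to_numpy()


def _expr(norm: ad.AnnData, mask: np.ndarray, genes: list[str]) -> np.ndarray:
    sub = norm[np.asarray(mask, dtype=bool), genes].X
    return sub.toarray() if sp.issparse(sub) else np.asarray(sub)


def _genes_of(genes) -> list[str]:
    return list(genes.genes) if isinstance(genes, DEGSelection) else list(genes)


def baseline_stats(norm: ad.AnnData, baseline_cells, genes) -> BaselineStats:
    """Zero-excluded per-gene mean/SD over the baseline cells.

    ``genes`` may be a :class:`DEGSelection` or a plain gene list.  Genes with
    fewer than two nonzero baseline values are flagged undefined and logged.
    """
    mask = np.asarray(baseline_cells, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty baseline cell set")
    gene_list = _genes_of(genes)
    if not gene_list:
        raise ValueError("empty gene set")
    missing = [g for g in gene_list if g not in norm.var_names]
    if missing:
        raise KeyError(f"genes not in the matrix: {missing[:5]}")
    X = _expr(norm, mask, gene_list)

    nz = X > 0
    k = nz.sum(axis=0).astype(float)
    s = np.where(nz, X, 0.0).sum(axis=0)
    ss = np.where(nz, X**2, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(k > 0, s / np.maximum(k, 1), np.nan)
        var = np.where(k > 1, (ss - s**2 / np.maximum(k, 1)) / np.maximum(k - 1, 1), np.nan)
    sigma = np.sqrt(np.maximum(var, 0.0))
    defined = k >= 2

    if not defined.any():
        raise ValueError("all genes are undefined in the baseline (fewer than 2 nonzero values)")
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("%d/%d genes undefined in baseline; dropped from the %%RRG denominator",
                    n_undef, len(gene_list))
    frame = pd.DataFrame(
        {"mu": mu, "sigma": sigma, "n_nonzero": k.astype(int), "defined": defined},
        index=pd.Index(gene_list, name="gene"),
    )
    return BaselineStats(stats=frame, n_baseline_cells=int(mask.sum()))


def rrg_per_cell(norm: ad.AnnData, cells, baseline: BaselineStats, genes=None) -> RRGResult:
    """%RRG per evaluated cell against a fixed baseline.

    A gene responds in a cell when its (zero-inclusive) log-normalized value
    strictly exceeds ``mu + sigma``; %RRG = 100 * responding / defined genes.
    """
    mask = np.asarray(cells, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty evaluated cell set")
    gene_list = _genes_of(genes) if genes is not None else list(baseline.stats.index)
    stats_sub = baseline.stats.loc[gene_list]
    defined = stats_sub["defined"].to_numpy()
    if defined.sum() == 0:
        raise ValueError("no baseline-defined genes to evaluate")
    use = [g for g, d in zip(gene_list, defined) if d]
    thr = (stats_sub.loc[use, "mu"] + stats_sub.loc[use, "sigma"]).to_numpy()

    X = _expr(norm, mask, use)
    responding = (X > thr[None, :]).sum(axis=1)
    n_defined = len(use)
    frame = pd.DataFrame(
        {
            "n_defined": n_defined,
            "n_responding": responding,
            "pct_rrg": 100.0 * responding / n_defined,
        },
        index=norm.obs_names[mask],
    )
    for col in ("population", "condition", "timepoint"):
        if col in norm.obs:
            frame[col] = norm.obs.loc[frame.index, col].to_numpy()
    return RRGResult(cells=frame, deg_set_size=len(gene_list), n_defined=n_defined)


def compare_rrg(group_a: RRGResult | pd.Series | np.ndarray,
                group_b: RRGResult | pd.Series | np.ndarray) -> CompareResult:
    """Two-sided Wilcoxon rank-sum comparison of two %RRG distributions."""
    va = group_a.cells["pct_rrg"].to_numpy() if isinstance(group_a, RRGResult) else np.asarray(group_a, float)
    vb = group_b.cells["pct_rrg"].to_numpy() if isinstance(group_b, RRGResult) else np.asarray(group_b, float)
    if va.size == 0 or vb.size == 0:
        raise ValueError("both groups must be non-empty")
    med_a, med_b = float(np.median(va)), float(np.median(vb))
    ratio = med_a / med_b if med_b != 0 else np.inf if med_a > 0 else np.nan
    pooled = np.concatenate([va, vb])
    if np.all(pooled == pooled[0]):
        u = va.size * vb.size / 2.0
        p = 1.0
    else:
        res = stats.mannwhitneyu(va, vb, alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
        u, p = float(res.statistic), float(res.pvalue)
    return CompareResult(median_a=med_a, median_b=med_b, median_ratio=ratio,
                         u_statistic=u, pvalue=min(p, 1.0), n_a=va.size, n_b=vb.size)


def bimodality(
    values,
    n_boot: int = 200,
    seed: int = 0,
    dip_alpha: float = 0.05,
    min_delta_bic: float = 10.0,
) -> BimodalityResult:
    """Joint dip-test + Gaussian-mixture assessment of %RRG bimodality.

    Declares a distribution bimodal when the bootstrap dip p-value falls below
    ``dip_alpha`` AND a 2-component Gaussian mixture beats 1 component by more
    than ``min_delta_bic`` BIC points.  Requires at least 10 values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("bimodality assessment requires at least 10 values")
    if np.all(x == x[0]):
        return BimodalityResult(dip=0.0, dip_pvalue=1.0, delta_bic=0.0,
                                modes=(float(x[0]),), bimodal=False)
    d, p = dip_pvalue(x, n_boot=n_boot, seed=seed)
    col = x.reshape(-1, 1)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(col)
    gm2 = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(col)
    delta = float(gm1.bic(col) - gm2.bic(col))  # positive favours 2 components
    modes = tuple(sorted(float(m) for m in gm2.means_.ravel()))
    return BimodalityResult(
        dip=d, dip_pvalue=p, delta_bic=delta, modes=modes,
        bimodal=bool(p < dip_alpha and delta > min_delta_bic),
    )
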