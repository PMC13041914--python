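"""Gene-signature module scoring, 0-1 rescaling, ternary lineage coordinates
and cell-cycle phase calls.

Module scores follow the Tirosh strategy popularised by Seurat's
AddModuleScore: genes are binned by their average expression across cells,
control genes are drawn per signature gene from the matching bin, and the
per-cell score is the mean expression of the signature genes minus the mean
expression of the pooled control genes.  The binning/draw parameters and seed
are recorded in the result so scores are reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "ModuleScoreResult",
    "module_score",
    "rescale01",
    "ternary_coords",
    "cell_cycle_phase",
]


@dataclass
class GeneSignature:
    """A named gene set (e.g. basal / luminal_progenitor / mature_luminal / S / G2M)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")

    def resolve(self, var_names: pd.Index) -> list[str]:
        """Members present in the gene table; unresolved members are reported."""
        present = [g for g in self.genes if g in var_names]
        missing = [g for g in self.genes if g not in var_names]
        if missing:
            logger.warning(
                "signature %r: %d/%d genes not in the gene table (e.g. %s)",
                self.name, len(missing), len(self.genes), missing[:3],
            )
        if not present:
            raise ValueError(f"no gene of signature {self.name!r} is resolvable")
        return present


@dataclass
class ModuleScoreResult:
    """Per-cell raw module scores with the control-binning provenance."""

    scores: pd.DataFrame  # cells x signatures
    n_bins: int
    n_ctrl: int
    seed: int
    controls: dict[str, dict[str, list[str]]] = field(default_factory=dict)


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def module_score(
    norm: ad.AnnData,
    signatures: GeneSignature | list[GeneSignature],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Tirosh-style signature score per cell.

    Genes are ranked by mean expression across all cells and split into
    ``n_bins`` equal-size bins.  For each signature gene, ``n_ctrl`` control
    genes are sampled without replacement from its bin (the whole bin is used
    when it holds at most ``n_ctrl`` genes).  The RNG protocol is fixed: one
    ``numpy.random.default_rng(seed)`` stream, signatures processed in the
    given order, each signature's resolved genes in list order.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be >= 1")
    if isinstance(signatures, GeneSignature):
        signatures = [signatures]
    X = _dense(norm.X)
    n_genes = norm.n_vars
    data_avg = X.mean(axis=0)
    order = np.argsort(data_avg, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = (np.arange(n_genes) * n_bins) // n_genes
    bin_members = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}
    gene_pos = {g: i for i, g in enumerate(norm.var_names)}

    rng = np.random.default_rng(seed)
    scores: dict[str, np.ndarray] = {}
    controls: dict[str, dict[str, list[str]]] = {}
    for sig in signatures:
        members = sig.resolve(norm.var_names)
        sig_idx = np.array([gene_pos[g] for g in members])
        ctrl_pool: list[np.ndarray] = []
        ctrl_record: dict[str, list[str]] = {}
        for g in members:
            bin_idx = bin_members[bin_of[gene_pos[g]]]
            if len(bin_idx) <= n_ctrl:
                drawn = bin_idx
            else:
                drawn = rng.choice(bin_idx, size=n_ctrl, replace=False)
            ctrl_pool.append(drawn)
            ctrl_record[g] = [norm.var_names[i] for i in drawn]
        pooled = np.concatenate(ctrl_pool)
        scores[sig.name] = X[:, sig_idx].mean(axis=1) - X[:, pooled].mean(axis=1)
        controls[sig.name] = ctrl_record

    frame = pd.DataFrame(scores, index=norm.obs_names)
    return ModuleScoreResult(scores=frame, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed, controls=controls)


def rescale01(scores: np.ndarray | pd.Series) -> np.ndarray:
    """Min-max rescale a score vector to [0, 1], independently per signature.

    A constant vector has no defined range; every cell is mapped to 0.5 and a
    warning is emitted.
    """
    values = np.asarray(scores, dtype=float)
    lo, hi = np.min(values), np.max(values)
    if hi == lo:
        warnings.warn("constant score vector: rescale01 is undefined, returning 0.5", stacklevel=2)
        return np.full(values.shape, 0.5)
    return (values - lo) / (hi - lo)


def ternary_coords(b, lp, ml) -> np.ndarray:
    """Project three rescaled lineage scores onto the 2-simplex, per cell.

    Each triple is divided by its sum; an all-zero triple carries no lineage
    information and is mapped to the centroid (1/3, 1/3, 1/3).
    """
    tri = np.column_stack([np.asarray(b, float), np.asarray(lp, float), np.asarray(ml, float)])
    if (tri < 0).any():
        raise ValueError("ternary_coords requires nonnegative (rescaled) scores")
    total = tri.sum(axis=1)
    out = np.full_like(tri, 1.0 / 3.0)
    nz = total > 0
    out[nz] = tri[nz] / total[nz, None]
    return out


def cell_cycle_phase(s_score, g2m_score) -> np.ndarray:
    """Assign G1/S/G2M per cell from the two cycle scores.

    Cells with both scores <= 0 are G1; otherwise the larger score wins, with
    exact ties broken toward S (logged).
    """
    s = np.asarray(s_score, dtype=float)
    g2m = np.asarray(g2m_score, dtype=float)
    if s.shape != g2m.shape:
        raise ValueError("score vectors must have the same length")
    phase = np.where(s >= g2m, "S", "G2M")
    phase = np.where((s <= 0) & (g2m <= 0), "G1", phase)
    ties = (s == g2m) & ((s > 0) | (g2m > 0))
    if ties.any():
        logger.info("%d exact S/G2M score ties broken toward S", int(ties.sum()))
    return phase.astype(object)
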