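"""End-to-end hormone-response analysis: normalize -> DE -> baseline -> %RRG.

One call runs the full contrast for a hormone/timepoint: log-normalization,
Wilcoxon DE of hormone-treated vs vehicle ERalpha+ cells, gating into the
upregulated DEG set, zero-excluded baseline estimation from timepoint-matched
vehicle ERalpha+ cells, %RRG for all four cell groups (treated/vehicle x
ERalpha+/-) against that single baseline, and the treated-vs-vehicle Wilcoxon
comparison within the ERalpha+ compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from . import degs, matrixops, rrg

__all__ = ["RRGAnalysis", "hormone_response_analysis"]


@dataclass
class RRGAnalysis:
    """Bundle of everything one hormone/timepoint contrast produces."""

    deg_table: pd.DataFrame | None
    deg_selection: degs.DEGSelection | None
    baseline: rrg.BaselineStats
    rrg_cells: pd.DataFrame  # per-cell %RRG with a 'group' column
    comparison: rrg.CompareResult  # treated ERalpha+ vs vehicle ERalpha+


def hormone_response_analysis(
    adata: ad.AnnData,
    hormone: str,
    timepoint: str,
    vehicle_label: str = "vehicle",
    population_pos: str = "ERpos",
    scale_factor: float = 1e4,
    padj_max: float = 0.05,
    min_abs_log2fc: float = 0.25,
    pseudocount: float = 1.0,
    deg_genes: list[str] | None = None,
    normalized: bool = False,
) -> RRGAnalysis:
    """Run the %RRG pipeline for one hormone and timepoint.

    ``deg_genes`` overrides the DE step with a fixed gene panel (e.g. for null
    calibration, where the DEG selection is empty by design).  Set
    ``normalized=True`` when ``adata`` already holds log-normalized values.
    """
    norm = adata if normalized else matrixops.lognormalize(adata, scale_factor)
    obs = norm.obs
    at_tp = (obs["timepoint"] == timepoint).to_numpy()
    is_pos = (obs["population"] == population_pos).to_numpy()
    treated = (obs["condition"] == hormone).to_numpy() & at_tp
    vehicle = (obs["condition"] == vehicle_label).to_numpy() & at_tp

    deg_table = None
    selection = None
    if deg_genes is None:
        deg_table = degs.run_de(norm, treated & is_pos, vehicle & is_pos, pseudocount)
        selection = degs.select_degs(deg_table, padj_max, min_abs_log2fc, direction="up")
        deg_genes = selection.genes
    if not deg_genes:
        raise ValueError("no upregulated DEGs passed the thresholds; cannot score %RRG")

    base = rrg.baseline_stats(norm, vehicle & is_pos, deg_genes)
    groups = {
        "treated_ERpos": treated & is_pos,
        "vehicle_ERpos": vehicle & is_pos,
        "treated_ERneg": treated & ~is_pos,
        "vehicle_ERneg": vehicle & ~is_pos,
    }
    frames = []
    results: dict[str, rrg.RRGResult] = {}
    for name, mask in groups.items():
        if mask.sum() == 0:
            continue
        res = rrg.rrg_per_cell(norm, mask, base)
        results[name] = res
        frame = res.cells.copy()
        frame["group"] = name
        frames.append(frame)
    comparison = rrg.compare_rrg(results["treated_ERpos"], results["vehicle_ERpos"])
    return RRGAnalysis(
        deg_table=deg_table,
        deg_selection=selection,
        baseline=base,
        rrg_cells=pd.concat(frames),
        comparison=comparison,
    )
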