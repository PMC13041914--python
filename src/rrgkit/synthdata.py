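"""Synthetic single-cell, gene-signature and nuclear-intensity generators.

The count generator emulates the experimental design the downstream analysis
assumes: organoid cells split into a hormone-sensing ERalpha+ subpopulation
(about one fifth of cells by default) and an ERalpha- remainder, profiled
under vehicle and hormone conditions at one or more timepoints.  Counts follow
a gamma-Poisson (negative-binomial) law per gene with lognormal per-cell size
factors, so zeros arise naturally from low means rather than from a separate
zero-inflation component.

Hormone response is planted per cell and per gene: in hormone-treated ERalpha+
cells each responsive gene's negative-binomial mean is multiplied by
``2**effect_log2fc`` with probability ``a_c``, the cell's latent activation
fraction.  ``a_c`` is coupled to a latent "co-regulator" covariate through a
Gaussian copula whose rank correlation targets ``coreg_rho``, and the covariate
is realised as an actual highly expressed synthetic gene (symbol ``Coreg1``),
so regulator-vs-%RRG association can be tested end to end on counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "TruthLabels",
    "generate_counts",
    "generate_signature_cells",
    "generate_intensity_table",
]

POP_POS = "ERpos"
POP_NEG = "ERneg"
COREG_SYMBOL = "Coreg1"


@dataclass
class SimConfig:
    """Parameters of the synthetic single-cell experiment.

    The defaults mirror the study design being emulated: ~20% ERalpha+ cells,
    vehicle vs hormone conditions at two timepoints, a few hundred planted
    hormone-upregulated genes, UMI depths of a few thousand per cell, and a
    bimodal responder/non-responder mixture of per-cell activation fractions.
    The magnitude of the per-gene hormone effect is a free parameter (the
    underlying study does not constrain it); 2x (``effect_log2fc=1``) is used
    as a clearly-detectable but not extreme default.
    """

    n_cells: int = 3000
    frac_erpos: float = 0.20
    n_genes: int = 2000
    n_responsive: int = 200
    depth_mean: float = 5000.0
    dispersion: float = 0.3
    effect_log2fc: float = 1.0
    responder_model: str = "bimodal"  # "uniform" or "bimodal"
    bimodal_high_weight: float = 0.5
    activation_low: float = 0.1
    activation_high: float = 0.7
    activation_jitter: float = 0.05
    coreg_rho: float = 0.5
    timepoints: tuple[str, ...] = ("4h", "16h")
    conditions: tuple[str, ...] = ("vehicle", "E2")
    vehicle_label: str = "vehicle"
    n_mito_genes: int = 10
    mito_expr_frac: float = 0.05
    coreg_expr_frac: float = 0.005
    resp_expr_frac: float = 0.05
    coreg_sigma: float = 0.6
    size_factor_sigma: float = 0.3
    gene_mean_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_genes <= 0:
            raise ValueError("n_cells must be >= 0 and n_genes > 0")
        for name in ("frac_erpos", "bimodal_high_weight", "activation_low",
                     "activation_high", "mito_expr_frac", "coreg_expr_frac",
                     "resp_expr_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_responsive > self.n_genes:
            raise ValueError("n_responsive cannot exceed n_genes")
        if self.n_responsive + self.n_mito_genes + 1 > self.n_genes:
            raise ValueError("n_genes too small for responsive + mito + co-regulator genes")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not -1.0 < self.coreg_rho < 1.0:
            raise ValueError("coreg_rho must lie in (-1, 1)")
        if self.responder_model not in ("uniform", "bimodal"):
            raise ValueError("responder_model must be 'uniform' or 'bimodal'")
        if self.vehicle_label not in self.conditions and self.n_cells > 0:
            # hormone-only designs are allowed; vehicle baselines then come
            # from a separate simulation
            pass


@dataclass
class TruthLabels:
    """Ground truth accompanying a simulated count matrix.

    ``cells`` carries population/condition/timepoint labels, the effective
    per-cell activation fraction (0 for all vehicle and all ERalpha- cells)
    and the latent co-regulator covariate.  ``genes`` flags the planted
    responsive genes, the co-regulator gene and mito genes, with the planted
    log2 effect per gene.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame


def _activation_from_uniform(u: np.ndarray, config: SimConfig) -> np.ndarray:
    """Map Uniform(0,1) draws to activation fractions, monotonically.

    For the bimodal model the mixture quantile function is used (low mode
    first), so activation is a monotone function of ``u`` and the Gaussian
    copula's rank correlation carries through exactly.
    """
    if config.responder_model == "uniform":
        return u.copy()
    w_hi = config.bimodal_high_weight
    w_lo = 1.0 - w_hi
    a = np.empty_like(u)
    lo = u < w_lo if w_lo > 0 else np.zeros(u.shape, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        u_lo = np.clip(u[lo] / max(w_lo, 1e-300), 1e-9, 1 - 1e-9)
        u_hi = np.clip((u[~lo] - w_lo) / max(w_hi, 1e-300), 1e-9, 1 - 1e-9)
    a[lo] = config.activation_low + config.activation_jitter * norm.ppf(u_lo)
    a[~lo] = config.activation_high + config.activation_jitter * norm.ppf(u_hi)
    return np.clip(a, 0.0, 1.0)


def _gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    symbols = np.array([f"Gene{i:05d}" for i in range(n)], dtype=object)
    mito = np.zeros(n, dtype=bool)
    mito[: config.n_mito_genes] = True
    for i in range(config.n_mito_genes):
        symbols[i] = f"mt-Sim{i + 1}"
    coreg_idx = config.n_mito_genes
    symbols[coreg_idx] = COREG_SYMBOL

    candidates = np.arange(coreg_idx + 1, n)
    responsive_idx = rng.choice(candidates, size=config.n_responsive, replace=False)
    responsive = np.zeros(n, dtype=bool)
    responsive[responsive_idx] = True

    # relative expression: lognormal across genes, with fixed transcriptome
    # mass shares for the mito block, the co-regulator gene and the responsive
    # panel.  Capping the responsive panel's baseline share (5% by default)
    # keeps hormone induction from inflating cell totals so much that depth
    # normalization visibly dilutes every other gene.
    base = rng.lognormal(mean=0.0, sigma=config.gene_mean_sigma, size=n)
    props = np.zeros(n)
    rest = ~(mito | responsive)
    rest[coreg_idx] = False
    mito_frac = config.mito_expr_frac if config.n_mito_genes else 0.0
    resp_frac = config.resp_expr_frac if config.n_responsive else 0.0
    rest_frac = 1.0 - mito_frac - resp_frac - config.coreg_expr_frac
    if rest_frac <= 0:
        raise ValueError("expression mass fractions exceed 1")
    if config.n_mito_genes:
        props[mito] = mito_frac * base[mito] / base[mito].sum()
    if config.n_responsive:
        props[responsive] = resp_frac * base[responsive] / base[responsive].sum()
    props[coreg_idx] = config.coreg_expr_frac
    props[rest] = rest_frac * base[rest] / base[rest].sum()

    return pd.DataFrame(
        {
            "gene_ids": [f"SIMG{i:05d}" for i in range(n)],
            "mito": mito,
            "responsive": responsive,
            "is_coreg": np.arange(n) == coreg_idx,
            "base_prop": props,
            "effect_log2fc": np.where(responsive, config.effect_log2fc, 0.0),
        },
        index=pd.Index(symbols, name="symbol"),
    )


def _cell_table(config: SimConfig) -> pd.DataFrame:
    """Deterministic condition/timepoint/population assignment.

    Cells are split as evenly as possible across the condition x timepoint
    design and, within each group, exactly ``round(frac_erpos * n_group)``
    cells are ERalpha+.  Determinism keeps group sizes exact and reproducible.
    """
    groups = [(c, t) for c in config.conditions for t in config.timepoints]
    n_g = len(groups)
    sizes = [config.n_cells // n_g + (1 if i < config.n_cells % n_g else 0) for i in range(n_g)]
    cond, tp, pop = [], [], []
    for (c, t), size in zip(groups, sizes):
        n_pos = int(round(config.frac_erpos * size))
        cond += [c] * size
        tp += [t] * size
        pop += [POP_POS] * n_pos + [POP_NEG] * (size - n_pos)
    return pd.DataFrame(
        {"condition": cond, "timepoint": tp, "population": pop},
        index=pd.Index([f"cell_{i:06d}" for i in range(config.n_cells)], name="barcode"),
    )


def generate_counts(config: SimConfig) -> tuple[ad.AnnData, TruthLabels]:
    """Simulate a UMI count matrix with planted hormone response.

    Counts are first drawn for every gene at baseline means (gamma-Poisson
    with per-cell size factors; the co-regulator gene additionally carries
    mean-one lognormal biological variation).  The per-cell activation
    fraction is then coupled, through a Gaussian copula on normal scores, to
    the *realized* log-normalized co-regulator expression -- the same quantity
    the association stage later measures -- so the planted rank correlation
    refers to an observable covariate, not an inaccessible latent.  Finally
    the responsive-gene entries of hormone-treated ERalpha+ cells are redrawn
    with each gene's mean multiplied by ``2**effect_log2fc`` on a per-cell
    Bernoulli(a_c) basis (with effect 0 the redraw reproduces the baseline
    law, so treated and vehicle cells stay exchangeable).

    Returns a cells-by-genes AnnData with sparse integer counts plus
    :class:`TruthLabels`.  Identical config (including seed) gives bitwise
    identical counts.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config, rng)
    cells = _cell_table(config)
    n_c = config.n_cells
    shape = 1.0 / config.dispersion

    treated = (cells["condition"] != config.vehicle_label).to_numpy()
    erpos = (cells["population"] == POP_POS).to_numpy()
    active = treated & erpos

    # per-cell size factors (mean-one lognormal) set expected depth
    sf = rng.lognormal(mean=-config.size_factor_sigma**2 / 2, sigma=config.size_factor_sigma, size=n_c)
    mu = np.outer(sf * config.depth_mean, genes["base_prop"].to_numpy())
    coreg_idx = int(np.flatnonzero(genes["is_coreg"].to_numpy())[0])
    if n_c:
        mu[:, coreg_idx] *= rng.lognormal(-config.coreg_sigma**2 / 2, config.coreg_sigma, size=n_c)

    counts = (
        rng.poisson(rng.gamma(shape, mu * config.dispersion)).astype(np.int32)
        if mu.size
        else np.zeros_like(mu, dtype=np.int32)
    )

    # couple activation to the realized depth-corrected co-regulator expression
    if n_c > 1:
        totals = np.maximum(counts.sum(axis=1), 1)
        proxy = np.log1p(counts[:, coreg_idx] * 1e4 / totals)
        ranks = pd.Series(proxy).rank(method="average").to_numpy()
        z_expr = norm.ppf((ranks - 0.375) / (n_c + 0.25))  # Blom normal scores
    else:
        z_expr = np.zeros(n_c)
    rho_p = 2.0 * math.sin(math.pi * config.coreg_rho / 6.0)
    z1 = rho_p * z_expr + math.sqrt(max(0.0, 1.0 - rho_p**2)) * rng.standard_normal(n_c)
    a_latent = _activation_from_uniform(norm.cdf(z1), config)
    activation = np.where(active, a_latent, 0.0)

    # planted effect: redraw responsive-gene entries of active cells with the
    # per-cell, per-gene Bernoulli(a_c) mean boost
    resp_idx = np.flatnonzero(genes["responsive"].to_numpy())
    if active.any() and resp_idx.size:
        act_rows = np.flatnonzero(active)
        hits = rng.random((act_rows.size, resp_idx.size)) < activation[act_rows, None]
        boost = np.where(hits, 2.0 ** config.effect_log2fc, 1.0)
        mu_eff = mu[np.ix_(act_rows, resp_idx)] * boost
        counts[np.ix_(act_rows, resp_idx)] = rng.poisson(
            rng.gamma(shape, mu_eff * config.dispersion)
        ).astype(np.int32)

    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=cells.copy(),
        var=genes[["gene_ids", "mito"]].copy(),
    )
    truth_cells = cells.copy()
    truth_cells["activation"] = activation
    truth_cells["coreg_latent"] = z_expr
    truth = TruthLabels(cells=truth_cells, genes=genes.drop(columns=["base_prop"]))
    return adata, truth


def generate_signature_cells(
    n_archetypes: int = 3,
    cells_per_archetype: int = 200,
    genes_per_module: int = 100,
    n_background_genes: int = 400,
    factor: float = 4.0,
    depth_mean: float = 10000.0,
    dispersion: float = 0.2,
    seed: int = 0,
) -> tuple[ad.AnnData, dict[str, list[str]]]:
    """Simulate lineage-archetype cells with disjoint over-expressed modules.

    Each archetype over-expresses its own gene module by ``factor`` on the
    negative-binomial mean scale (per-cell depth is held comparable by
    renormalising the mean vector).  Module sizes default to 100 genes,
    matching the scale of curated lineage signatures.  The first three
    archetypes are named after the mammary lineage programs (basal, luminal
    progenitor, mature luminal).  Returns the count AnnData (obs column
    ``archetype``) and the gene sets.
    """
    if n_archetypes < 3:
        raise ValueError("at least 3 lineage archetypes are required")
    if factor <= 0:
        raise ValueError("factor must be positive")
    rng = np.random.default_rng(seed)
    names = ["basal", "luminal_progenitor", "mature_luminal"] + [
        f"archetype{i}" for i in range(3, n_archetypes)
    ]
    names = names[:n_archetypes]

    n_genes = n_archetypes * genes_per_module + n_background_genes
    symbols = [f"Sig{i:05d}" for i in range(n_genes)]
    modules = {
        names[k]: symbols[k * genes_per_module : (k + 1) * genes_per_module]
        for k in range(n_archetypes)
    }

    base = rng.lognormal(0.0, 1.0, size=n_genes)
    props = base / base.sum()
    n_cells = n_archetypes * cells_per_archetype
    sf = rng.lognormal(-0.3**2 / 2, 0.3, size=n_cells)
    mu = np.outer(sf * depth_mean, props)
    archetype = np.repeat(names, cells_per_archetype)
    for k, name in enumerate(names):
        rows = slice(k * cells_per_archetype, (k + 1) * cells_per_archetype)
        cols = slice(k * genes_per_module, (k + 1) * genes_per_module)
        mu[rows, cols] *= factor
    mu *= (sf * depth_mean)[:, None] / mu.sum(axis=1)[:, None]  # keep depth comparable

    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    counts = rng.poisson(lam).astype(np.int32)
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(
            {"archetype": pd.Categorical(archetype)},
            index=pd.Index([f"cell_{i:06d}" for i in range(n_cells)], name="barcode"),
        ),
        var=pd.DataFrame(
            {"gene_ids": [f"SIGG{i:05d}" for i in range(n_genes)], "mito": False},
            index=pd.Index(symbols, name="symbol"),
        ),
    )
    return adata, modules


def generate_intensity_table(
    n_organoids: int = 20,
    nuclei_per_organoid: int = 500,
    planted_pos_frac_er: float = 0.5,
    planted_pos_frac_pr: float = 0.25,
    co_pos_rule: str = "nested",
    separation: float = 5.0,
    sigma: float = 0.25,
    background_median: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-nucleus median intensities for marker-positivity tests.

    Each channel is a two-component lognormal mixture (background vs positive,
    medians separated by ``separation``-fold).  Under the default ``nested``
    co-positivity rule PR+ nuclei are a subset of ERalpha+ nuclei, emulating
    the near-total restriction of PR to the ERalpha+ compartment.  Truth
    columns ``truth_er_pos`` / ``truth_pr_pos`` are included.
    """
    for name, v in (("planted_pos_frac_er", planted_pos_frac_er), ("planted_pos_frac_pr", planted_pos_frac_pr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if co_pos_rule not in ("nested", "independent"):
        raise ValueError("co_pos_rule must be 'nested' or 'independent'")
    if co_pos_rule == "nested" and planted_pos_frac_pr > planted_pos_frac_er:
        raise ValueError("nested rule requires planted_pos_frac_pr <= planted_pos_frac_er")
    if separation <= 1:
        raise ValueError("separation must exceed 1")

    rng = np.random.default_rng(seed)
    n = n_organoids * nuclei_per_organoid
    er_pos = rng.random(n) < planted_pos_frac_er
    if co_pos_rule == "nested":
        p_given_er = planted_pos_frac_pr / planted_pos_frac_er if planted_pos_frac_er > 0 else 0.0
        pr_pos = er_pos & (rng.random(n) < p_given_er)
    else:
        pr_pos = rng.random(n) < planted_pos_frac_pr

    def channel(pos: np.ndarray) -> np.ndarray:
        mu = np.where(pos, math.log(background_median * separation), math.log(background_median))
        return np.exp(rng.normal(mu, sigma))

    return pd.DataFrame(
        {
            "nucleus_id": np.tile(np.arange(nuclei_per_organoid), n_organoids),
            "organoid_id": np.repeat([f"org{i:03d}" for i in range(n_organoids)], nuclei_per_organoid),
            "ER": channel(er_pos),
            "PR": channel(pr_pos),
            "truth_er_pos": er_pos,
            "truth_pr_pos": pr_pos,
        }
    )
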