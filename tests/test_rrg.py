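import numpy as np
import pytest

from rrgkit import matrixops, rrg, synthdata
from conftest import toy_adata


def brute_force_rrg(X, baseline_mask, eval_mask):
    """Naive double-loop %RRG: zero-excluded baseline mean + 1 sample SD, strict >."""
    thresholds = []
    defined = []
    for g in range(X.shape[1]):
        vals = X[baseline_mask, g]
        nz = vals[vals > 0]
        if len(nz) >= 2:
            thresholds.append(nz.mean() + nz.std(ddof=1))
            defined.append(g)
    out = []
    for c in np.flatnonzero(eval_mask):
        responding = sum(1 for t, g in zip(thresholds, defined) if X[c, g] > t)
        out.append(100.0 * responding / len(defined))
    return np.array(out)


class TestBaselineStats:
    def test_hand_computed_zero_excluded_moments(self):
        # values [0, 2, 3, 4]: zeros excluded -> mu 3, sample SD 1
        adata = toy_adata(np.array([[0.0], [2.0], [3.0], [4.0]]))
        bs = rrg.baseline_stats(adata, [True] * 4, ["g0"])
        row = bs.stats.loc["g0"]
        assert row["mu"] == pytest.approx(3.0)
        assert row["sigma"] == pytest.approx(1.0)
        assert row["n_nonzero"] == 3 and bool(row["defined"])

    def test_all_zero_gene_undefined(self):
        adata = toy_adata(np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]]))
        bs = rrg.baseline_stats(adata, [True] * 3, ["g0", "g1"])
        assert not bs.stats.loc["g0", "defined"]
        assert list(bs.defined_genes) == ["g1"]

    def test_single_nonzero_undefined(self):
        adata = toy_adata(np.array([[0.0, 1.0], [5.0, 2.0], [0.0, 3.0]]))
        bs = rrg.baseline_stats(adata, [True] * 3, ["g0", "g1"])
        assert not bs.stats.loc["g0", "defined"]

    def test_errors(self):
        adata = toy_adata(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="empty baseline"):
            rrg.baseline_stats(adata, [False] * 3, ["g0"])
        with pytest.raises(ValueError, match="undefined"):
            rrg.baseline_stats(adata, [True] * 3, ["g0", "g1"])


class TestRRGPerCell:
    def make(self, eval_row):
        # hand-built baseline with thresholds mu + sigma = [4.0, 1.0, 2.5]
        import pandas as pd

        stats_frame = pd.DataFrame(
            {
                "mu": [3.0, 0.6, 2.0],
                "sigma": [1.0, 0.4, 0.5],
                "n_nonzero": [4, 4, 4],
                "defined": [True, True, True],
            },
            index=pd.Index(["g0", "g1", "g2"], name="gene"),
        )
        bs = rrg.BaselineStats(stats=stats_frame, n_baseline_cells=4)
        adata = toy_adata(np.array([eval_row]))
        return adata, bs

    def test_direct_evaluation_with_strict_threshold(self):
        adata, bs = self.make([4.5, 0.0, 2.5])
        res = rrg.rrg_per_cell(adata, [True], bs)
        # only g0 exceeds its threshold; the exact-threshold g2 does not (strict >)
        assert res.cells["n_responding"].iloc[0] == 1
        assert res.cells["pct_rrg"].iloc[0] == pytest.approx(100 / 3)

    def test_cell_at_baseline_mean_scores_zero(self):
        adata, bs = self.make(list(np.array([3.0, 0.6, 2.0])))
        res = rrg.rrg_per_cell(adata, [True], bs)
        assert res.cells["pct_rrg"].iloc[0] == 0.0

    def test_cell_far_above_scores_hundred(self):
        adata, bs = self.make(list(np.array([3.0, 0.6, 2.0]) + 1.5 * np.array([1.0, 0.4, 0.5])))
        res = rrg.rrg_per_cell(adata, [True], bs)
        assert res.cells["pct_rrg"].iloc[0] == 100.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_cells = rng.integers(6, 14)
            n_genes = rng.integers(2, 8)
            X = np.round(rng.exponential(1.0, size=(n_cells, n_genes)) * (rng.random((n_cells, n_genes)) > 0.4), 3)
            mask_b = np.zeros(n_cells, dtype=bool)
            mask_b[: n_cells // 2] = True
            adata = toy_adata(X)
            try:
                bs = rrg.baseline_stats(adata, mask_b, list(adata.var_names))
            except ValueError:
                continue  # all genes undefined in this draw
            res = rrg.rrg_per_cell(adata, ~mask_b, bs)
            np.testing.assert_allclose(
                res.cells["pct_rrg"].to_numpy(), brute_force_rrg(X, mask_b, ~mask_b), atol=1e-9
            )

    def test_range_and_constant_denominator(self, small_sim, small_norm):
        _, adata, truth = small_sim
        obs = small_norm.obs
        vehicle_pos = ((obs["condition"] == "vehicle") & (obs["population"] == "ERpos")).to_numpy()
        panel = list(truth.genes.index[truth.genes["responsive"]])
        bs = rrg.baseline_stats(small_norm, vehicle_pos, panel)
        res = rrg.rrg_per_cell(small_norm, ~vehicle_pos, bs)
        assert res.cells["pct_rrg"].between(0, 100).all()
        assert res.cells["n_defined"].nunique() == 1


class TestCompareRRG:
    def test_identical_groups(self):
        vals = np.full(20, 12.5)
        res = rrg.compare_rrg(vals, vals.copy())
        assert res.pvalue == 1.0 and res.median_ratio == pytest.approx(1.0)

    def test_swap_inverts_ratio_keeps_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(30) * 50 + 10, rng.random(30) * 50
        r1, r2 = rrg.compare_rrg(a, b), rrg.compare_rrg(b, a)
        assert r1.pvalue == pytest.approx(r2.pvalue)
        assert r1.median_ratio == pytest.approx(1 / r2.median_ratio)

    def test_detects_planted_shift(self, small_sim, small_norm):
        _, adata, truth = small_sim
        obs = small_norm.obs
        pos = (obs["population"] == "ERpos").to_numpy()
        treated = (obs["condition"] == "E2").to_numpy()
        vehicle = (obs["condition"] == "vehicle").to_numpy()
        panel = list(truth.genes.index[truth.genes["responsive"]])
        bs = rrg.baseline_stats(small_norm, vehicle & pos, panel)
        ra = rrg.rrg_per_cell(small_norm, treated & pos, bs)
        rb = rrg.rrg_per_cell(small_norm, vehicle & pos, bs)
        res = rrg.compare_rrg(ra, rb)
        assert res.median_a > res.median_b
        assert res.pvalue < 0.05

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            rrg.compare_rrg(np.array([]), np.array([1.0]))


class TestBimodality:
    def test_unimodal_gaussian_not_declared(self):
        rng = np.random.default_rng(3)
        res = rrg.bimodality(rng.normal(30, 5, 500), seed=3)
        assert not res.bimodal

    def test_separated_mixture_declared(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(10, 2, 250), rng.normal(22, 2, 250)])
        res = rrg.bimodality(x, seed=4)
        assert res.bimodal
        assert res.modes[0] < 15 < res.modes[1]

    def test_constant_vector(self):
        res = rrg.bimodality(np.full(20, 7.0), seed=0)
        assert res.dip == 0.0 and not res.bimodal

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError, match="at least 10"):
            rrg.bimodality(np.arange(5))


class TestNullAndMonotonicity:
    def test_erneg_rrg_invariant_to_effect(self):
        medians = []
        for effect in (0.0, 2.0):
            cfg = synthdata.SimConfig(
                n_cells=600, n_genes=400, n_responsive=60, frac_erpos=0.5,
                conditions=("vehicle", "E2"), timepoints=("4h",),
                effect_log2fc=effect, seed=77,
            )
            adata, truth = synthdata.generate_counts(cfg)
            norm = matrixops.lognormalize(adata)
            obs = norm.obs
            pos = (obs["population"] == "ERpos").to_numpy()
            vehicle = (obs["condition"] == "vehicle").to_numpy()
            panel = list(truth.genes.index[truth.genes["responsive"]])
            bs = rrg.baseline_stats(norm, vehicle & pos, panel)
            res = rrg.rrg_per_cell(norm, ~vehicle & ~pos, bs)
            medians.append(np.median(res.cells["pct_rrg"]))
        assert abs(medians[0] - medians[1]) < 2.0

    def test_median_rrg_monotone_in_effect(self):
        meds = []
        for effect in (0.0, 1.0, 2.0):
            cfg = synthdata.SimConfig(
                n_cells=600, n_genes=400, n_responsive=60, frac_erpos=0.5,
                conditions=("vehicle", "E2"), timepoints=("4h",),
                effect_log2fc=effect, responder_model="uniform", seed=55,
            )
            adata, truth = synthdata.generate_counts(cfg)
            norm = matrixops.lognormalize(adata)
            obs = norm.obs
            pos = (obs["population"] == "ERpos").to_numpy()
            vehicle = (obs["condition"] == "vehicle").to_numpy()
            panel = list(truth.genes.index[truth.genes["responsive"]])
            bs = rrg.baseline_stats(norm, vehicle & pos, panel)
            res = rrg.rrg_per_cell(norm, ~vehicle & pos, bs)
            meds.append(np.median(res.cells["pct_rrg"]))
        assert meds[0] <= meds[1] <= meds[2]
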