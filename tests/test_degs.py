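import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rrgkit import degs, matrixops, pipeline, synthdata
from conftest import toy_adata


def exact_rank_sum_p(x, y):
    """Two-sided exact permutation p for the rank-sum test (enumeration oracle)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, pooled = len(x), np.concatenate([x, y])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    lo = min(u_obs, nx * (n - nx) - u_obs)
    hi = max(u_obs, nx * (n - nx) - u_obs)
    count = total = 0
    for comb in itertools.combinations(range(n), nx):
        u = ranks[list(comb)].sum() - nx * (nx + 1) / 2
        count += (u <= lo) or (u >= hi)
        total += 1
    return count / total


class TestWilcoxonGeneTest:
    def test_all_ties_give_p_one(self):
        adata = toy_adata(np.ones((6, 3)))
        p = degs.wilcoxon_gene_test(adata, [True] * 3 + [False] * 3, [False] * 3 + [True] * 3)
        np.testing.assert_allclose(p, 1.0)

    def test_small_groups_against_enumeration(self):
        # A=[1,2], B=[3,4]: exact two-sided p = 2/6
        assert exact_rank_sum_p([1, 2], [3, 4]) == pytest.approx(1 / 3)
        adata = toy_adata(np.array([[1.0], [2.0], [3.0], [4.0]]))
        p = degs.wilcoxon_gene_test(adata, [True, True, False, False], [False, False, True, True])
        # the normal approximation is compared against the exact oracle
        assert abs(p[0] - 1 / 3) < 0.1

    def test_label_swap_symmetry(self, small_norm):
        mask_a = np.zeros(small_norm.n_obs, dtype=bool)
        mask_a[:40] = True
        mask_b = np.zeros(small_norm.n_obs, dtype=bool)
        mask_b[40:90] = True
        p1 = degs.wilcoxon_gene_test(small_norm, mask_a, mask_b)
        p2 = degs.wilcoxon_gene_test(small_norm, mask_b, mask_a)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_overlap_and_empty_errors(self, small_norm):
        mask = np.zeros(small_norm.n_obs, dtype=bool)
        mask[:5] = True
        with pytest.raises(ValueError, match="overlap"):
            degs.wilcoxon_gene_test(small_norm, mask, mask)
        with pytest.raises(ValueError, match="non-empty"):
            degs.wilcoxon_gene_test(small_norm, mask, np.zeros(small_norm.n_obs, dtype=bool))

    def test_close_to_exact_enumeration_for_moderate_groups(self):
        # tie-free data, group sizes 5..8: asymptotic within 0.02 of enumeration
        # (at sizes <= 4 the worst-case deviation provably exceeds 0.02)
        rng = np.random.default_rng(2)
        worst = 0.0
        for _ in range(15):
            na, nb = rng.integers(5, 9), rng.integers(5, 9)
            x, y = rng.normal(size=na), rng.normal(size=nb)
            adata = toy_adata(np.concatenate([x, y]).reshape(-1, 1))
            mask_a = np.arange(na + nb) < na
            p = degs.wilcoxon_gene_test(adata, mask_a, ~mask_a)[0]
            worst = max(worst, abs(p - exact_rank_sum_p(x, y)))
        assert worst < 0.02


class TestLog2FC:
    def test_identical_groups_zero(self):
        adata = toy_adata(np.tile([[1.0], [2.0]], (2, 1)))
        lfc = degs.log2fc(adata, [True, True, False, False], [False, False, True, True])
        np.testing.assert_allclose(lfc, 0.0, atol=1e-12)

    def test_closed_form(self):
        # de-logged means 3 vs 1 with pc=1 -> log2(4/2) = 1
        a = np.log1p(np.array([[3.0], [3.0]]))
        b = np.log1p(np.array([[1.0], [1.0]]))
        adata = toy_adata(np.vstack([a, b]))
        lfc = degs.log2fc(adata, [True, True, False, False], [False, False, True, True])
        assert lfc[0] == pytest.approx(1.0)

    def test_antisymmetry(self, small_norm):
        mask_a = np.arange(small_norm.n_obs) < 50
        lfc_ab = degs.log2fc(small_norm, mask_a, ~mask_a)
        lfc_ba = degs.log2fc(small_norm, ~mask_a, mask_a)
        np.testing.assert_allclose(lfc_ab, -lfc_ba, atol=1e-12)


class TestBHAdjust:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(degs.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(degs.bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(degs.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            degs.bh_adjust([0.5, 1.5])

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_in_range(self, pvals):
        adj = degs.bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all((adj >= 0) & (adj <= 1))


class TestSelectDegs:
    def make_table(self, padj, lfc):
        return pd.DataFrame({"padj": padj, "log2fc": lfc},
                            index=[f"g{i}" for i in range(len(padj))])

    def test_exact_padj_boundary_excluded(self):
        table = self.make_table([0.05], [1.0])
        assert degs.select_degs(table).genes == []

    def test_exact_lfc_boundary_included(self):
        table = self.make_table([0.01], [0.25])
        assert degs.select_degs(table).genes == ["g0"]

    def test_direction_up_excludes_negative(self):
        table = self.make_table([0.01, 0.01], [0.5, -0.5])
        assert degs.select_degs(table, direction="up").genes == ["g0"]
        assert degs.select_degs(table, direction="down").genes == ["g1"]
        assert degs.select_degs(table, direction="both").genes == ["g0", "g1"]

    def test_empty_table(self):
        assert degs.select_degs(self.make_table([], [])).genes == []


class TestPower:
    def test_planted_genes_recovered_at_strong_effect(self):
        # fully activated responders: >= 90% of planted genes reach the up-DEG set
        cfg = synthdata.SimConfig(
            n_cells=800, n_genes=800, n_responsive=100, frac_erpos=0.5,
            conditions=("vehicle", "E2"), timepoints=("4h",), effect_log2fc=1.0,
            responder_model="bimodal", bimodal_high_weight=1.0,
            activation_low=0.1, activation_high=0.95,
            depth_mean=10000.0, gene_mean_sigma=1.0, seed=11,
        )
        adata, truth = synthdata.generate_counts(cfg)
        res = pipeline.hormone_response_analysis(adata, "E2", "4h")
        planted = set(truth.genes.index[truth.genes["responsive"]])
        recovered = planted & set(res.deg_selection.genes)
        assert len(recovered) / len(planted) >= 0.90

    def test_deg_count_monotone_in_effect(self):
        counts = []
        for effect in (0.25, 1.0, 2.0):
            n_sel = []
            for seed in range(5):
                cfg = synthdata.SimConfig(
                    n_cells=400, n_genes=300, n_responsive=50, frac_erpos=0.5,
                    conditions=("vehicle", "E2"), timepoints=("4h",),
                    effect_log2fc=effect, responder_model="uniform", seed=100 + seed,
                )
                adata, _ = synthdata.generate_counts(cfg)
                norm = matrixops.lognormalize(adata)
                obs = norm.obs
                pos = (obs["population"] == "ERpos").to_numpy()
                table = degs.run_de(
                    norm,
                    ((obs["condition"] == "E2").to_numpy() & pos),
                    ((obs["condition"] == "vehicle").to_numpy() & pos),
                )
                n_sel.append(len(degs.select_degs(table).genes))
            counts.append(np.mean(n_sel))
        assert counts[0] <= counts[1] <= counts[2]
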