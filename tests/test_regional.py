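import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from braakstage import (
    ExpressionMatrix,
    GeneRegionImportance,
    ImportanceVector,
    PathwayBlock,
    PathwayPanel,
    SyntheticConfig,
    build_gene_region_importance,
    coexpression_summary,
    cross_stage_overlap,
    generate_cohort,
    heatmap_table,
    row_normalize,
    spearman_pair,
    stage_region_profile,
)


def _grid(values, genes=None, regions=None, normalization="raw"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    regions = regions or [f"R{j}" for j in range(values.shape[1])]
    return GeneRegionImportance(
        stage=0, frame=pd.DataFrame(values, index=genes, columns=regions),
        normalization=normalization,
    )


class TestRowNormalize:
    def test_hand_worked(self):
        out = row_normalize(_grid([[0, 2, 4]]))
        np.testing.assert_allclose(out.frame.to_numpy(), [[0, 0.5, 1]])

    def test_zero_row_stays_zero(self):
        out = row_normalize(_grid([[0, 0, 0], [1, 2, 4]]))
        np.testing.assert_array_equal(out.frame.to_numpy()[0], 0.0)

    def test_nonzero_rows_attain_one(self):
        rng = np.random.default_rng(0)
        out = row_normalize(_grid(rng.random((10, 4)) + 0.01))
        np.testing.assert_allclose(out.frame.to_numpy().max(axis=1), 1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            row_normalize(_grid([[-1, 2]]))


class TestStageRegionProfile:
    def test_hand_worked_minmax(self):
        grid = _grid(
            [[0.1, 0.3, 0.5], [0.3, 0.5, 0.7]], normalization="row_normalized"
        )
        prof = stage_region_profile(grid)
        np.testing.assert_allclose(prof.mean_importance, [0.2, 0.4, 0.6])
        np.testing.assert_allclose(prof.profile, [0, 0.5, 1])

    def test_constant_means_map_to_zero(self):
        grid = _grid([[0.5, 0.5], [0.5, 0.5]], normalization="row_normalized")
        np.testing.assert_array_equal(stage_region_profile(grid).profile, 0.0)

    def test_single_nonzero_region(self):
        grid = _grid([[0.0, 0.4, 0.0]], normalization="row_normalized")
        np.testing.assert_allclose(stage_region_profile(grid).profile, [0, 1, 0])

    def test_single_region_rejected(self):
        grid = _grid([[1.0]], normalization="row_normalized")
        with pytest.raises(ValueError, match="2 regions"):
            stage_region_profile(grid)

    def test_raw_input_rejected(self):
        with pytest.raises(ValueError, match="row-normalized"):
            stage_region_profile(_grid([[1.0, 2.0]]))

    def test_scale_invariance_of_profile(self):
        rng = np.random.default_rng(1)
        raw = rng.random((8, 5)) + 0.01
        scaled = raw.copy()
        scaled[3] *= 37.0  # rescale one gene's whole row
        p1 = stage_region_profile(row_normalize(_grid(raw))).profile
        p2 = stage_region_profile(row_normalize(_grid(scaled))).profile
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestCrossStageOverlap:
    def _lists(self, shared=0):
        lists = {
            s: [f"s{s}_g{i}" for i in range(20)] for s in range(3)
        }
        for i in range(shared):
            lists[1][i] = lists[0][i]
        return lists

    def test_disjoint(self):
        o = cross_stage_overlap(self._lists(0))
        assert (o.n_selected, o.n_unique, o.n_multi_stage) == (60, 60, 0)
        assert o.overlap_fraction == 0.0

    def test_single_shared_gene_gives_one_sixtieth(self):
        o = cross_stage_overlap(self._lists(1))
        assert o.n_unique == 59
        assert o.overlap_fraction == pytest.approx(1 / 60)
        assert o.pairwise_shared[(0, 1)] == ["s0_g0"]

    def test_three_identical_lists(self):
        lists = {s: [f"g{i}" for i in range(20)] for s in range(3)}
        o = cross_stage_overlap(lists)
        assert (o.n_unique, o.n_multi_stage) == (20, 20)
        assert o.overlap_fraction == pytest.approx(20 / 60)

    def test_duplicate_within_list_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cross_stage_overlap({0: ["a", "a"], 1: ["b", "c"]})


class TestHeatmapTable:
    def _iv(self, mapping, region):
        genes = list(mapping)
        return ImportanceVector(
            genes, np.array([mapping[g] for g in genes], dtype=float), 0, region
        )

    def test_single_region_matches_top_k_order(self):
        iv = self._iv({"a": 1.0, "b": 3.0, "c": 2.0}, "R1")
        table = heatmap_table({"R1": iv}, k=3)
        assert list(table.index) == ["b", "c", "a"]
        np.testing.assert_allclose(table["R1"], 1.0)  # row-normalized singles

    def test_absent_gene_is_zero_and_columns_sorted(self):
        iv1 = self._iv({"a": 5.0, "b": 1.0}, "R1")
        iv2 = self._iv({"c": 2.0}, "R2")
        table = heatmap_table({"R1": iv1, "R2": iv2}, k=3)
        assert list(table.columns) == ["R1", "R2"]  # summed importance 6 > 2
        assert table.loc["a", "R2"] == 0.0
        assert table.loc["c", "R1"] == 0.0

    def test_rows_restricted_to_overall_top_k(self):
        iv1 = self._iv({"a": 5.0, "b": 4.0, "c": 0.1}, "R1")
        iv2 = self._iv({"d": 4.5, "e": 0.2, "c": 0.1}, "R2")
        table = heatmap_table({"R1": iv1, "R2": iv2}, k=3)
        assert list(table.index) == ["a", "d", "b"]


class TestSpearman:
    def test_rank_formula_oracle_small_n(self):
        rng = np.random.default_rng(2)
        for n in (4, 5, 6, 7, 8):
            x = rng.permutation(n).astype(float)  # tie-free
            y = rng.permutation(n).astype(float)
            rho, _ = spearman_pair(x, y)
            d = stats.rankdata(x) - stats.rankdata(y)
            oracle = 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_p_perfect_monotone(self):
        x = np.arange(6, dtype=float)
        rho, p = spearman_pair(x, x * 2 + 1)
        assert rho == 1.0
        # only the identity and the full reversal reach |rho| = 1
        assert p == pytest.approx(2 / 720)


class TestCoexpression:
    def _expr(self, values, genes):
        return ExpressionMatrix(
            "R", genes, [f"s{i}" for i in range(values.shape[0])], values
        )

    def test_perfect_monotone_pair(self):
        x = np.arange(20, dtype=float)
        expr = self._expr(np.column_stack([x, np.exp(x / 5)]), ["bm", "p1"])
        s = coexpression_summary(expr, "bm", PathwayPanel("syn", ["p1"]))
        assert s.n_tested == 1
        assert s.max_rho == pytest.approx(1.0)
        assert s.n_significant == 1

    def test_min_overlap_skips_small_pairs(self):
        x = np.arange(4, dtype=float)
        expr = self._expr(np.column_stack([x, x]), ["bm", "p1"])
        s = coexpression_summary(expr, "bm", PathwayPanel("syn", ["p1"]), min_overlap=5)
        assert s.n_tested == 0 and s.n_significant == 0

    def test_absent_biomarker_rejected(self):
        expr = self._expr(np.ones((6, 1)) * np.arange(6)[:, None], ["g1"])
        with pytest.raises(ValueError, match="absent"):
            coexpression_summary(expr, "nope", PathwayPanel("p", ["g1"]))

    def test_independent_noise_rarely_significant(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(60, 4))
        expr = self._expr(vals, ["bm", "n1", "n2", "n3"])
        s = coexpression_summary(expr, "bm", PathwayPanel("noise", ["n1", "n2", "n3"]))
        assert s.n_tested == 3
        assert s.n_significant <= 1  # binomial(3, 0.05) expectation

    def test_planted_pathway_block_recovered(self):
        cfg = SyntheticConfig(
            n_per_stage=(20, 20, 20), regions=("MTG",), n_genes=120, n_planted=0,
            effect_size=0.0,
            pathway_blocks=(PathwayBlock("mito", n_panel_genes=6, correlation=0.6),),
            seed=11,
        )
        matrices, _, truth = generate_cohort(cfg)
        block = truth.pathway["MTG"][0]
        s = coexpression_summary(
            matrices["MTG"], block["biomarker"],
            PathwayPanel(block["panel_name"], block["panel_genes"]),
        )
        assert s.n_tested == 6
        assert s.n_significant / s.n_tested >= 0.8
        assert s.mean_abs_rho > 0.3
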