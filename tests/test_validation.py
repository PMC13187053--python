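import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braakstage import (
    ImportanceVector,
    ModelHyperparams,
    assign_confidence,
    bh_fdr,
    cv_stability,
    gene_confidence_table,
    permutation_pvalues,
    permutation_significance,
    stability_from_fold_lists,
    validation_score,
)

TIER_ORDER = {"Excluded": 0, "Low": 1, "Medium": 2, "High": 3}


def _signal_data(effect=3.0, n=60, g=15, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1, 2], n // 3)
    X = rng.normal(size=(len(y), g))
    for s in range(3):
        X[y == s, s] += effect  # gene s is the stage-s marker
    return X, y


class TestStability:
    def test_fold_count_arithmetic(self):
        folds = [["a", "b"], ["a", "b"], ["a", "c"], ["a", "b"], ["a", "b"]]
        stab = stability_from_fold_lists(folds, ["a", "b", "c", "d"])
        assert stab["a"] == 1.0
        assert stab["b"] == pytest.approx(0.8)
        assert stab["c"] == pytest.approx(0.2)
        assert stab["d"] == 0.0

    def test_stability_times_k_is_integer(self, tiny_hp):
        X, y = _signal_data(seed=1)
        stab = cv_stability(X, y, K=5, k_top=3, hp=tiny_hp, seed=0)
        np.testing.assert_allclose(
            (stab["stability"] * 5) % 1.0, 0.0, atol=1e-12
        )
        assert stab["stability"].between(0, 1).all()

    def test_strong_planted_gene_fully_stable(self, tiny_hp):
        X, y = _signal_data(effect=3.0, seed=2)
        stab = cv_stability(X, y, K=5, k_top=3, hp=tiny_hp, seed=0)
        stab = stab.set_index(["stage", "gene"])
        for s in range(3):
            assert stab.loc[(s, f"f{s}"), "stability"] == 1.0
            assert stab.loc[(s, f"f{s}"), "mean_rank"] == 1.0

    def test_unstratifiable_rejected(self, tiny_hp):
        X = np.zeros((9, 2))
        y = np.repeat([0, 1, 2], 3)
        with pytest.raises(ValueError, match="stratified"):
            cv_stability(X, y, K=5, hp=tiny_hp)


class TestValidationScore:
    def test_weighted_sum_values(self):
        assert validation_score(1, 1, 1) == pytest.approx(1.0)
        assert validation_score(0, 0, 0) == 0.0
        assert validation_score(0.5, 0.5, 1.0) == pytest.approx(0.65)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            validation_score(1.2, 0.5, 0.5)
        with pytest.raises(ValueError):
            validation_score(0.5, -0.1, 0.5)

    @given(
        st.floats(0, 0.9), st.floats(0, 0.9), st.floats(0, 0.9),
        st.floats(0.01, 0.1),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_each_argument(self, a, b, c, delta):
        base = validation_score(a, b, c)
        for bumped in (
            (min(a + delta, 1), b, c),
            (a, min(b + delta, 1), c),
            (a, b, min(c + delta, 1)),
        ):
            if bumped != (a, b, c):
                assert validation_score(*bumped) > base


class TestAssignConfidence:
    DIST = np.arange(1.0, 101.0)  # percentiles land on known values

    def test_quoted_threshold_cases(self):
        at = lambda q: np.percentile(self.DIST, q)
        assert assign_confidence(0.8, at(80), self.DIST) == "High"
        assert assign_confidence(0.6, at(60), self.DIST) == "Medium"
        assert assign_confidence(0.4, at(30), self.DIST) == "Low"
        assert assign_confidence(0.2, at(99), self.DIST) == "Excluded"

    def test_strict_percentile_boundary(self):
        # exactly AT the 75th percentile is not "above" it
        at75 = np.percentile(self.DIST, 75)
        assert assign_confidence(0.9, at75, self.DIST) == "Medium"

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            assign_confidence(0.9, 1.0, [])

    @given(
        st.floats(0, 1), st.floats(0, 100),
        st.floats(0, 0.5), st.floats(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_stability_and_importance(self, stab, imp, dstab, dimp):
        lo = TIER_ORDER[assign_confidence(stab, imp, self.DIST)]
        hi = TIER_ORDER[
            assign_confidence(min(stab + dstab, 1.0), imp + dimp, self.DIST)
        ]
        assert hi >= lo


class TestGeneConfidenceTable:
    def test_score_formula_and_tier_consistency(self, fitted):
        conf = fitted.validate(K=3, k_top=10)
        recomputed = (
            0.4 * conf["train_norm"] + 0.3 * conf["test_norm"] + 0.3 * conf["stability"]
        )
        np.testing.assert_allclose(conf["validation_score"], recomputed, atol=1e-12)
        assert conf["validation_score"].between(0, 1).all()
        assert set(conf["confidence"]).issubset({"High", "Medium", "Low", "Excluded"})
        # tiers recompute from their definition
        for stage, grp in conf.groupby("stage"):
            dist = grp["test_importance_raw"].to_numpy()
            for _, row in grp.iterrows():
                assert row["confidence"] == assign_confidence(
                    row["stability"], row["test_importance_raw"], dist
                )


class TestBH:
    def test_hand_worked_ladder(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_on_small_grids(self):
        def brute(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                q[i] = running
            return q

        grid = [0.005, 0.05, 0.2, 0.5, 1.0]
        for length in (1, 2, 3):
            for combo in itertools.product(grid, repeat=length):
                np.testing.assert_allclose(bh_fdr(combo), brute(combo), atol=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(4, 7))
            np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)


class TestPermutation:
    def test_pvalue_formula(self):
        nulls = np.arange(99, dtype=float).reshape(99, 1)
        assert permutation_pvalues([1000.0], nulls)[0] == pytest.approx(0.01)
        assert permutation_pvalues([-1.0], nulls)[0] == pytest.approx(1.0)

    def test_small_b_rejected(self, tiny_hp):
        X, y = _signal_data()
        with pytest.raises(ValueError, match="19"):
            permutation_significance(X, y, B=5, hp=tiny_hp)

    def test_strong_gene_hits_resolution_floor(self, tiny_hp):
        X, y = _signal_data(effect=4.0, n=45, g=8, seed=3)
        res = permutation_significance(X, y, B=19, hp=tiny_hp, seed=0)
        assert res["p_value"].between(1 / 20, 1).all()
        marker_p = res.set_index("gene").loc[["f0", "f1", "f2"], "p_value"]
        np.testing.assert_allclose(marker_p, 1 / 20)
        np.testing.assert_allclose(
            res["q_value"], bh_fdr(res["p_value"]), atol=1e-12
        )

    def test_gene_subsample_is_deterministic(self, tiny_hp):
        X, y = _signal_data(n=30, g=12, seed=4)
        r1 = permutation_significance(X, y, B=19, hp=tiny_hp, seed=5, gene_subsample=6)
        r2 = permutation_significance(X, y, B=19, hp=tiny_hp, seed=5, gene_subsample=6)
        assert len(r1) == 6
        pd.testing.assert_frame_equal(r1, r2)
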