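import itertools
import json
import math

import numpy as np
import pytest
import xgboost as xgb

from braakstage import (
    BraakStagingModel,
    ModelHyperparams,
    PathwayBlock,
    SyntheticConfig,
    align_region,
    generate_cohort,
    sample_subject_map,
)


@pytest.fixture(scope="session")
def tiny_hp():
    """Fast hyperparameters for structural tests (not the study settings)."""
    return ModelHyperparams(n_estimators=40, max_depth=4, learning_rate=0.1)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SyntheticConfig(
        regions=("Hipp", "PCC"),
        n_genes=150,
        n_planted=5,
        effect_size=2.5,
        pathway_blocks=(PathwayBlock(panel_name="synaptic", n_panel_genes=6, correlation=0.6),),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def hipp_dataset(small_cohort):
    matrices, clinical, _ = small_cohort
    m = matrices["Hipp"]
    return align_region(m, clinical, sample_subject_map(m))


@pytest.fixture(scope="session")
def fitted(hipp_dataset, tiny_hp):
    return BraakStagingModel(hipp_dataset, hyperparams=tiny_hp, seed=11).fit()


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive-subset Shapley values for a boosted-tree
# model, with the conditional expectation following the dumped tree
# structure (cover-weighted descent for features outside the coalition).


def _cond_exp(node, x, coalition):
    if "leaf" in node:
        return node["leaf"]
    f = int(node["split"][1:])
    if f in coalition:
        # the library evaluates splits in float32; match it exactly
        cid = (
            node["yes"]
            if np.float32(x[f]) < np.float32(node["split_condition"])
            else node["no"]
        )
        child = next(c for c in node["children"] if c["nodeid"] == cid)
        return _cond_exp(child, x, coalition)
    left, right = node["children"]
    cl, cr = left["cover"], right["cover"]
    return (cl * _cond_exp(left, x, coalition) + cr * _cond_exp(right, x, coalition)) / (cl + cr)


def brute_force_tree_shapley(booster: xgb.Booster, x, class_index: int, n_features: int,
                             n_classes: int = 3) -> np.ndarray:
    """Shapley values by exhaustive subset enumeration over all features."""
    trees = [json.loads(t) for t in booster.get_dump(dump_format="json", with_stats=True)]
    class_trees = [t for i, t in enumerate(trees) if i % n_classes == class_index]

    def value(coalition):
        return sum(_cond_exp(t, x, coalition) for t in class_trees)

    phi = np.zeros(n_features)
    feats = range(n_features)
    for f in feats:
        others = [o for o in feats if o != f]
        for size in range(len(others) + 1):
            for subset in itertools.combinations(others, size):
                w = (
                    math.factorial(size)
                    * math.factorial(n_features - size - 1)
                    / math.factorial(n_features)
                )
                phi[f] += w * (value(set(subset) | {f}) - value(set(subset)))
    return phi
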