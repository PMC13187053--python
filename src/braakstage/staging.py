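"""Braak-stage label engineering, data splitting, SMOTE balancing and the
gradient-boosted staging classifier.

The classification target is the three-way grouping of the Braak
neurofibrillary-tangle score: Early (Braak 0-II), Mid (Braak III-IV) and
Late (Braak V-VI).  Models are XGBoost multiclass soft-probability
ensembles trained single-threaded for reproducibility.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import xgboost as xgb
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EXCLUDED",
    "STAGE_NAMES",
    "ModelHyperparams",
    "PerformanceReport",
    "TrainedStageModel",
    "braak_to_stage",
    "stratified_split",
    "smote_balance",
    "train_classifier",
    "evaluate",
]

#: Sentinel returned by :func:`braak_to_stage` for missing Braak scores.
EXCLUDED = -1

STAGE_NAMES = {0: "Early", 1: "Mid", 2: "Late"}
N_STAGES = 3


def braak_to_stage(braak) -> int:
    """Map a Braak score (0-6, or missing) to a stage label.

    Braak 0-2 -> 0 (Early), 3-4 -> 1 (Mid), 5-6 -> 2 (Late).  Missing
    values (None or NaN) return :data:`EXCLUDED`; scores outside [0, 6]
    raise ``ValueError``.
    """
    if braak is None or (isinstance(braak, float) and np.isnan(braak)):
        return EXCLUDED
    b = int(braak)
    if b != braak or not 0 <= b <= 6:
        raise ValueError(f"Braak score must be an integer in [0, 6], got {braak!r}")
    if b <= 2:
        return 0
    if b <= 4:
        return 1
    return 2


@dataclass(frozen=True)
class ModelHyperparams:
    """XGBoost hyperparameters for the three-class staging model."""

    n_estimators: int = 100
    max_depth: int = 10
    learning_rate: float = 0.005
    subsample: float = 0.5
    colsample_bytree: float = 0.5
    reg_alpha: float = 0.1
    reg_lambda: float = 0.5
    objective: str = "multi:softprob"
    seed: int = 0

    def __post_init__(self):
        if self.n_estimators <= 0 or self.max_depth <= 0:
            raise ValueError("n_estimators and max_depth must be positive")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        for name in ("subsample", "colsample_bytree", "reg_alpha", "reg_lambda"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_seed(self, seed: int) -> "ModelHyperparams":
        return replace(self, seed=int(seed))


@dataclass
class TrainedStageModel:
    """A fitted staging classifier plus the gene order it was fit with."""

    estimator: xgb.XGBClassifier
    gene_ids: list
    classes: tuple = (0, 1, 2)

    @property
    def booster(self) -> xgb.Booster:
        return self.estimator.get_booster()

    def _check_genes(self, gene_ids):
        if gene_ids is not None and list(gene_ids) != list(self.gene_ids):
            raise ValueError("gene order does not match the order used at fit time")

    def predict_proba(self, X, gene_ids=None) -> np.ndarray:
        self._check_genes(gene_ids)
        return self.estimator.predict_proba(np.asarray(X, dtype=np.float32))

    def predict(self, X, gene_ids=None) -> np.ndarray:
        return np.argmax(self.predict_proba(X, gene_ids), axis=1)

    def predict_margin(self, X, gene_ids=None) -> np.ndarray:
        """Per-class raw margins (the log-odds scale SHAP values live on)."""
        self._check_genes(gene_ids)
        dm = xgb.DMatrix(np.asarray(X, dtype=np.float32))
        return self.booster.predict(dm, output_margin=True)


def _derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed below 2**31 from a master seed and string tokens."""
    h = hashlib.blake2s(digest_size=4)
    h.update(str(int(seed)).encode())
    for t in tokens:
        h.update(b"/" + str(t).encode())
    return int.from_bytes(h.digest(), "little") % (2**31)


def stratified_split(y, train_frac: float = 0.7, seed: int = 0):
    """Stratified train/test partition with a largest-remainder policy.

    Per-class training counts are the class share of ``round(train_frac*n)``
    with fractional remainders resolved largest-first, so the overall
    training size is exactly ``round(train_frac * n)``.

    Returns ``(train_idx, test_idx)`` as sorted integer arrays; they are
    disjoint and exhaustive.
    """
    y = np.asarray(y)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        bad = classes[counts < 2].tolist()
        raise ValueError(f"classes with fewer than 2 samples cannot be split: {bad}")
    n_train_total = int(round(train_frac * len(y)))
    exact = counts * train_frac
    base = np.floor(exact).astype(int)
    # keep at least one sample of each class on both sides
    base = np.clip(base, 1, counts - 1)
    remainder = exact - np.floor(exact)
    deficit = n_train_total - base.sum()
    order = np.argsort(-remainder, kind="stable")
    take = base.copy()
    i = 0
    while deficit > 0 and i < len(order):
        c = order[i]
        if take[c] < counts[c] - 1:
            take[c] += 1
            deficit -= 1
        i += 1
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls, n_take in zip(classes, take):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(len(idx))
        train_parts.append(idx[perm[:n_take]])
        test_parts.append(idx[perm[n_take:]])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    return train_idx, test_idx


def smote_balance(X, y, k_neighbors: int = 5, seed: int = 0):
    """Balance classes by SMOTE: equalize every class to the majority count.

    Synthetic rows are convex combinations ``x + u * (x_nn - x)`` of a
    minority sample and one of its ``k`` nearest same-class neighbours
    (``u`` uniform on [0, 1]).  Original rows are preserved verbatim and
    come first in the returned arrays; ``k`` is clamped to
    ``minority_count - 1``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        bad = classes[counts < 2].tolist()
        raise ValueError(f"cannot interpolate classes with a single sample: {bad}")
    n_target = counts.max()
    if np.all(counts == n_target):
        return X, y
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls, count in zip(classes, counts):
        n_needed = n_target - count
        if n_needed == 0:
            continue
        Xc = X[y == cls]
        k = min(k_neighbors, count - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        # drop self-neighbour in column 0
        neighbours = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, count, size=n_needed)
        pick = rng.integers(0, k, size=n_needed)
        u = rng.uniform(0.0, 1.0, size=n_needed)
        anchor = Xc[base]
        partner = Xc[neighbours[base, pick]]
        new_X.append(anchor + u[:, None] * (partner - anchor))
        new_y.append(np.full(n_needed, cls, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)


def train_classifier(X, y, hp: ModelHyperparams | None = None, gene_ids=None) -> TrainedStageModel:
    """Fit the three-class XGBoost staging model.

    Training is single-threaded with a fixed seed so repeated fits on the
    same data are bit-identical.
    """
    hp = hp or ModelHyperparams()
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if len(np.unique(y)) < N_STAGES:
        raise ValueError("training labels must contain all three stages")
    est = xgb.XGBClassifier(
        objective=hp.objective,
        n_estimators=hp.n_estimators,
        max_depth=hp.max_depth,
        learning_rate=hp.learning_rate,
        subsample=hp.subsample,
        colsample_bytree=hp.colsample_bytree,
        reg_alpha=hp.reg_alpha,
        reg_lambda=hp.reg_lambda,
        tree_method="hist",
        n_jobs=1,
        random_state=hp.seed,
    )
    est.fit(X, y)
    if gene_ids is None:
        gene_ids = [f"f{i}" for i in range(X.shape[1])]
    return TrainedStageModel(estimator=est, gene_ids=list(gene_ids))


@dataclass
class PerformanceReport:
    """Held-out test metrics for one region's staging model."""

    accuracy: float
    auc_macro: float
    f1_per_class: tuple
    f1_macro: float
    missing_classes: tuple = field(default=())

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "auc_macro": self.auc_macro,
            "f1_macro": self.f1_macro,
        }
        for c, f1 in enumerate(self.f1_per_class):
            d[f"f1_class{c}"] = f1
        if self.missing_classes:
            d["missing_classes"] = list(self.missing_classes)
        return d


def evaluate(model: TrainedStageModel, X_test, y_test) -> PerformanceReport:
    """Accuracy, macro one-vs-rest AUC and per-class F1 on held-out data.

    If a class is absent from ``y_test`` its AUC is undefined; the report
    then carries ``auc_macro = nan`` and names the missing classes.
    """
    y_test = np.asarray(y_test)
    proba = model.predict_proba(X_test)
    y_pred = np.argmax(proba, axis=1)
    acc = accuracy_score(y_test, y_pred)
    f1_pc = f1_score(y_test, y_pred, labels=list(range(N_STAGES)), average=None, zero_division=0)
    f1_macro = float(np.mean(f1_pc))
    present = np.unique(y_test)
    missing = tuple(c for c in range(N_STAGES) if c not in present)
    if missing:
        auc = float("nan")
    else:
        auc = roc_auc_score(y_test, proba, multi_class="ovr", average="macro")
    return PerformanceReport(
        accuracy=float(acc),
        auc_macro=float(auc),
        f1_per_class=tuple(float(v) for v in f1_pc),
        f1_macro=f1_macro,
        missing_classes=missing,
    )
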