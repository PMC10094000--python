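"""Classification heads: the boosted-tree hybrid and six reference baselines.

The hybrid pipeline trains the residual backbone end-to-end, freezes it,
extracts 512-dim pooled embeddings, grid-searches the boosted-tree head's
``num_leaves`` and ``learning_rate`` by stratified cross-validated accuracy
on the training features, and fits the selected model. Test data never
enters any stage of fitting.

The baselines (RBF-SVM, random forest, 3-NN, XGBoost, classical-scaling +
SVM, and a one-hidden-layer backprop network) consume the per-timepoint
last-20-second rows; each row is classified independently, with optional
majority voting per measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from enoseml.backbone import (
    Backbone,
    BackboneConfig,
    TrainConfig,
    extract_features,
    train_backbone,
)

__all__ = [
    "GridSpec",
    "HybridModel",
    "BaselineSpec",
    "grid_search_gbdt",
    "fit_gbdt",
    "fit_hybrid",
    "predict_hybrid",
    "fit_baseline",
    "predict_baseline",
    "BASELINE_KINDS",
]

#: Boosted-tree rounds for every gradient-boosted model (head and baselines).
N_BOOST_ROUNDS = 100


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid for the boosted-tree head.

    Defaults are the published search ranges: five leaf counts times five
    shrinkage values, selected by stratified k-fold CV accuracy.
    """

    num_leaves_grid: tuple[int, ...] = (8, 16, 32, 64, 128)
    learning_rate_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 0.5, 1.0)
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if not self.num_leaves_grid or not self.learning_rate_grid:
            raise ValueError("grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _make_gbdt(num_leaves: int, learning_rate: float, seed: int) -> LGBMClassifier:
    return LGBMClassifier(
        num_leaves=num_leaves,
        learning_rate=learning_rate,
        n_estimators=N_BOOST_ROUNDS,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
        min_child_samples=5,
    )


def grid_search_gbdt(
    features: np.ndarray,
    labels: Sequence[str],
    grid: GridSpec | None = None,
    seed: int = 0,
) -> tuple[tuple[int, float], pd.DataFrame]:
    """Exhaustive grid search of (num_leaves, learning_rate) by CV accuracy.

    Returns the winning pair and the full CV table. Ties are broken toward
    the smaller ``num_leaves``, then the smaller ``learning_rate``, so the
    result does not depend on grid enumeration order. If the rarest class
    has fewer members than ``cv_folds``, the fold count is reduced with a
    warning.
    """
    grid = grid or GridSpec()
    features = np.asarray(features)
    y = np.asarray(labels)
    if len(features) < grid.cv_folds:
        raise ValueError("need at least cv_folds samples")
    _, counts = np.unique(y, return_counts=True)
    folds = int(min(grid.cv_folds, counts.min()))
    if folds < grid.cv_folds:
        warnings.warn(
            f"smallest class has {counts.min()} members; reducing CV folds "
            f"from {grid.cv_folds} to {folds}",
            stacklevel=2,
        )
    if folds < 2:
        raise ValueError("smallest class must have at least 2 members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(features, y))
    records = []
    for nl in grid.num_leaves_grid:
        for lr in grid.learning_rate_grid:
            accs = []
            for tr, va in splits:
                model = _make_gbdt(nl, lr, seed)
                model.fit(features[tr], y[tr])
                accs.append(float((model.predict(features[va]) == y[va]).mean()))
            records.append(
                {
                    "num_leaves": nl,
                    "learning_rate": lr,
                    "cv_accuracy": float(np.mean(accs)),
                }
            )
    table = pd.DataFrame.from_records(records)
    best_row = table.sort_values(
        ["cv_accuracy", "num_leaves", "learning_rate"],
        ascending=[False, True, True],
        kind="stable",
    ).iloc[0]
    best = (int(best_row["num_leaves"]), float(best_row["learning_rate"]))
    return best, table


def fit_gbdt(
    features: np.ndarray,
    labels: Sequence[str],
    grid: GridSpec | None = None,
    seed: int = 0,
) -> tuple[LGBMClassifier, tuple[int, float], pd.DataFrame]:
    """Grid-search then fit the boosted-tree classifier on all given rows."""
    best, table = grid_search_gbdt(features, labels, grid, seed)
    model = _make_gbdt(best[0], best[1], seed)
    model.fit(np.asarray(features), np.asarray(labels))
    return model, best, table


@dataclass
class HybridModel:
    """Frozen backbone + fitted boosted-tree head."""

    backbone: Backbone
    gbdt: LGBMClassifier
    best_params: tuple[int, float]
    cv_table: pd.DataFrame
    seed: int


def fit_hybrid(
    X: np.ndarray,
    labels: Sequence[str],
    backbone_cfg: BackboneConfig | None = None,
    train_cfg: TrainConfig | None = None,
    grid: GridSpec | None = None,
    seed: int = 0,
) -> HybridModel:
    """Train the full hybrid pipeline on tensorized measurements.

    ``X`` is (n, 10, 10, 10). The backbone is trained with its linear head,
    then frozen; its 512-dim embeddings of the training set feed the
    grid-searched boosted-tree head. No stage sees anything but the
    training data.
    """
    train_cfg = train_cfg or TrainConfig(seed=seed)
    backbone = train_backbone(X, list(labels), train_cfg, backbone_cfg)
    feats = extract_features(backbone, X)
    gbdt, best, table = fit_gbdt(feats, labels, grid, seed)
    return HybridModel(
        backbone=backbone, gbdt=gbdt, best_params=best, cv_table=table, seed=seed
    )


def predict_hybrid(model: HybridModel, X: np.ndarray) -> np.ndarray:
    """Predict labels for tensorized measurements."""
    feats = extract_features(model.backbone, X)
    return np.asarray(model.gbdt.predict(feats))


# ---------------------------------------------------------------------------
# Baselines on last-20 rows
# ---------------------------------------------------------------------------

BASELINE_KINDS = ("svm_rbf", "random_forest", "knn", "xgb", "mds_svm", "bpnn")


@dataclass(frozen=True)
class BaselineSpec:
    """A baseline classifier and its hyperparameters.

    Defaults are the published settings: RBF-SVM with C=100, gamma=1 (the
    winners of a C x gamma grid search); a 10-tree random forest with
    sqrt-features per split; 3-nearest-neighbours; an XGBoost model with the
    boosted-tree grid defaults; classical-scaling-to-3-dims + SVM; and a
    backprop network with one hidden layer of 64 rectified units.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS:
            raise ValueError(
                f"unknown baseline kind {self.kind!r}; expected one of {BASELINE_KINDS}"
            )


class _ClassicalScalingSVM:
    """Classical (Torgerson) scaling into a low-dim embedding, then RBF-SVM.

    Classical scaling of Euclidean distances coincides with projection onto
    the top principal axes, which gives a natural out-of-sample map: new
    rows are centred with the training mean and projected onto the same
    axes before classification.
    """

    def __init__(self, n_components: int = 3, C: float = 100.0, gamma: float = 1.0):
        self.n_components = n_components
        self.svm = SVC(C=C, gamma=gamma, kernel="rbf")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_ClassicalScalingSVM":
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        self.axes_ = vt[: self.n_components]
        self.svm.fit(Xc @ self.axes_.T, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=np.float64) - self.mean_
        return self.svm.predict(Xc @ self.axes_.T)


class _XGBWrapper:
    """XGBoost with string-label round-trip."""

    def __init__(self, seed: int, num_leaves: int = 16, learning_rate: float = 0.1):
        self.model = XGBClassifier(
            n_estimators=N_BOOST_ROUNDS,
            max_leaves=num_leaves,
            grow_policy="lossguide",
            learning_rate=learning_rate,
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )

    def fit(self, X, y):
        self.classes_ = np.array(sorted(set(y)))
        lut = {c: i for i, c in enumerate(self.classes_)}
        self.model.fit(X, np.array([lut[v] for v in y]))
        return self

    def predict(self, X):
        return self.classes_[self.model.predict(X)]


def _build_baseline(spec: BaselineSpec, seed: int):
    p = spec.params
    if spec.kind == "svm_rbf":
        return SVC(C=p.get("C", 100.0), gamma=p.get("gamma", 1.0), kernel="rbf")
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.get("n_trees", 10),
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=p.get("k", 3))
    if spec.kind == "xgb":
        return _XGBWrapper(
            seed,
            num_leaves=p.get("num_leaves", 16),
            learning_rate=p.get("learning_rate", 0.1),
        )
    if spec.kind == "mds_svm":
        return _ClassicalScalingSVM(
            n_components=p.get("n_components", 3),
            C=p.get("C", 100.0),
            gamma=p.get("gamma", 1.0),
        )
    if spec.kind == "bpnn":
        return MLPClassifier(
            hidden_layer_sizes=p.get("hidden", (64,)),
            learning_rate_init=p.get("learning_rate", 1e-3),
            max_iter=p.get("max_iter", 300),
            random_state=seed,
        )
    raise ValueError(spec.kind)  # pragma: no cover - guarded by BaselineSpec


def fit_baseline(
    rows: np.ndarray, labels: Sequence[str], spec: BaselineSpec, seed: int = 0
):
    """Fit a baseline on per-timepoint 10-vectors."""
    model = _build_baseline(spec, seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        model.fit(np.asarray(rows), np.asarray(labels))
    return model


def predict_baseline(
    model,
    rows: np.ndarray,
    source_ids: Sequence[str] | None = None,
    vote_per_measurement: bool = False,
) -> np.ndarray:
    """Predict labels for per-timepoint rows.

    By default each row is classified independently. With
    ``vote_per_measurement`` (requires ``source_ids``) every row of a
    measurement receives the majority label over that measurement's rows;
    ties break toward the lexicographically smaller label.
    """
    pred = np.asarray(model.predict(np.asarray(rows)))
    if not vote_per_measurement:
        return pred
    if source_ids is None:
        raise ValueError("vote_per_measurement requires source_ids")
    ids = np.asarray(source_ids)
    out = pred.copy()
    for mid in pd.unique(ids):
        mask = ids == mid
        values, counts = np.unique(pred[mask], return_counts=True)
        out[mask] = values[counts.argmax()]
    return out
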