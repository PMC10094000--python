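"""Confusion matrices, the five-metric suite, and the experiment harness.

Metrics are derived from a C x C confusion matrix (rows = true class,
columns = predicted) by one-vs-rest marginalization:

* accuracy = trace / N;
* sensitivity = macro-averaged recall (mean of per-class TP / (TP + FN));
* precision = macro-averaged (mean of per-class TP / (TP + FP));
* F1 = mean of per-class harmonic means of precision and recall;
* Cohen's kappa = (p0 - pe) / (1 - pe), with p0 the accuracy and
  pe = sum_c rowsum_c * colsum_c / N^2 the marginal chance agreement.

With balanced test classes, macro sensitivity equals accuracy exactly —
which is why the two coincide in day-split evaluations of a balanced
protocol.

The harness mirrors the study structure: an ablation comparing the boosted
trees alone (last-20 rows), the backbone alone (its linear head) and the
full hybrid on one split, and per-dataset model-comparison experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import sklearn.metrics

from enoseml.backbone import BackboneConfig, TrainConfig, predict_backbone
from enoseml.classify import (
    BaselineSpec,
    GridSpec,
    fit_baseline,
    fit_gbdt,
    fit_hybrid,
    predict_baseline,
    predict_hybrid,
)
from enoseml.data import MeasurementSet, SplitSpec, assemble_dataset, day_split
from enoseml.features import last20_matrix, to_tensor_set

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ExperimentReport",
    "confusion_matrix",
    "compute_metrics",
    "evaluate_predictions",
    "run_ablation",
    "run_experiment",
]

METRIC_NAMES = ("accuracy", "sensitivity", "precision", "f1", "kappa")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (C, C) ints; rows true, columns predicted
    labels: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Count (true, predicted) pairs over a fixed label ordering."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if labels is None:
        labels = sorted(set(y_true))
    labels = list(labels)
    unseen = set(y_pred) - set(labels)
    if unseen:
        raise ValueError(f"predicted label(s) outside the label set: {sorted(unseen)}")
    counts = sklearn.metrics.confusion_matrix(y_true, y_pred, labels=labels)
    return ConfusionMatrix(counts=counts.astype(np.int64), labels=labels)


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    kappa: float
    per_class_f1: dict[str, float]
    p0: float
    pe: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The five-metric suite from a confusion matrix.

    Classes absent from the truth (empty rows) are excluded from the macro
    averages with a warning.
    """
    counts = cm.counts.astype(np.float64)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    tp = np.diag(counts)
    present = row > 0
    if not present.all():
        absent = [cm.labels[i] for i in np.flatnonzero(~present)]
        warnings.warn(
            f"class(es) with no true items excluded from macro averages: {absent}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, tp / row, np.nan)
        prec = np.where(col > 0, tp / col, 0.0)  # no predictions => precision 0
        f1 = np.where(
            (prec + recall) > 0, 2 * prec * recall / (prec + recall), 0.0
        )
    accuracy = float(tp.sum() / n)
    p0 = accuracy
    pe = float((row * col).sum() / n**2)
    kappa = (p0 - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    per_class_f1 = {
        cm.labels[i]: float(f1[i]) for i in np.flatnonzero(present)
    }
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=float(np.nanmean(np.where(present, recall, np.nan))),
        precision=float(np.mean(prec[present])),
        f1=float(np.mean(f1[present])),
        kappa=float(kappa),
        per_class_f1=per_class_f1,
        p0=p0,
        pe=pe,
    )


def evaluate_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str] | None = None
) -> MetricsReport:
    return compute_metrics(confusion_matrix(y_true, y_pred, labels))


# ---------------------------------------------------------------------------
# Experiment harness
# ---------------------------------------------------------------------------


@dataclass
class ExperimentReport:
    """Per-model metrics on one dataset variant and split."""

    dataset_variant: str
    split: SplitSpec
    seed: int
    metrics: dict[str, MetricsReport]
    config_echo: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = {
            model: report.as_dict() for model, report in self.metrics.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]

    def per_class_f1_table(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            {m: r.per_class_f1 for m, r in self.metrics.items()}, orient="index"
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.table().rename_axis("model").to_csv(path)
        txt = path.with_suffix(".txt")
        with open(txt, "w") as fh:
            fh.write(
                f"dataset variant: {self.dataset_variant}   seed: {self.seed}\n"
                f"train days: {sorted(self.split.train_days)}\n"
                f"test days: {sorted(self.split.test_days)}\n\n"
            )
            fh.write(self.table().round(4).to_string())
            fh.write("\n\nper-class F1\n")
            fh.write(self.per_class_f1_table().round(4).to_string())
            fh.write("\n")


def _default_train_cfg(seed: int) -> TrainConfig:
    return TrainConfig(seed=seed)


def run_ablation(
    dataset: MeasurementSet,
    split: SplitSpec | None = None,
    train_cfg: TrainConfig | None = None,
    grid: GridSpec | None = None,
    seed: int = 0,
    variant: str = "C",
) -> ExperimentReport:
    """The three-arm ablation on one day split.

    Arms: boosted trees alone on per-timepoint last-20 rows; the backbone
    alone through its linear head; and the full hybrid. All three see the
    identical split and are scored with the five metrics.
    """
    split = split or SplitSpec()
    train_cfg = train_cfg or _default_train_cfg(seed)
    train, test = day_split(dataset, split)
    labels = sorted(set(dataset.labels()))

    # arm 1: boosted trees on steady-state rows
    Xtr_rows, ytr_rows, _ = last20_matrix(train)
    Xte_rows, yte_rows, _ = last20_matrix(test)
    gbdt, _, _ = fit_gbdt(Xtr_rows, ytr_rows, grid, seed)
    gbdt_metrics = evaluate_predictions(yte_rows, gbdt.predict(Xte_rows), labels)

    # arms 2 and 3 share one trained backbone
    Xtr, ytr, _ = to_tensor_set(train)
    Xte, yte, _ = to_tensor_set(test)
    hybrid = fit_hybrid(Xtr, ytr, train_cfg=train_cfg, grid=grid, seed=seed)
    backbone_metrics = evaluate_predictions(
        yte, predict_backbone(hybrid.backbone, Xte), labels
    )
    hybrid_metrics = evaluate_predictions(yte, predict_hybrid(hybrid, Xte), labels)

    return ExperimentReport(
        dataset_variant=variant,
        split=split,
        seed=seed,
        metrics={
            "gbdt": gbdt_metrics,
            "resnet": backbone_metrics,
            "resnet_gbm": hybrid_metrics,
        },
        config_echo={"train_cfg": train_cfg.__dict__, "grid": (grid or GridSpec()).__dict__},
    )


#: Model names accepted by :func:`run_experiment`.
EXPERIMENT_MODELS = ("resnet_gbm", "svm", "rf", "knn", "xgb", "mds_svm", "bpnn")

_BASELINE_SPEC = {
    "svm": BaselineSpec("svm_rbf"),
    "rf": BaselineSpec("random_forest"),
    "knn": BaselineSpec("knn"),
    "xgb": BaselineSpec("xgb"),
    "mds_svm": BaselineSpec("mds_svm"),
    "bpnn": BaselineSpec("bpnn"),
}


def run_experiment(
    mset: MeasurementSet,
    dataset_variant: str,
    models: Sequence[str] = EXPERIMENT_MODELS,
    split: SplitSpec | None = None,
    train_cfg: TrainConfig | None = None,
    grid: GridSpec | None = None,
    seed: int = 0,
) -> ExperimentReport:
    """Compare models on one dataset variant with a day-based split.

    Baselines are fitted and scored on per-timepoint last-20 rows; the
    hybrid on tensorized full measurements.
    """
    split = split or SplitSpec()
    train_cfg = train_cfg or _default_train_cfg(seed)
    dataset = assemble_dataset(mset, dataset_variant)
    train, test = day_split(dataset, split)
    labels = sorted(set(dataset.labels()))
    metrics: dict[str, MetricsReport] = {}
    rows_cached = None
    for model in models:
        if model == "resnet_gbm":
            Xtr, ytr, _ = to_tensor_set(train)
            Xte, yte, _ = to_tensor_set(test)
            hybrid = fit_hybrid(Xtr, ytr, train_cfg=train_cfg, grid=grid, seed=seed)
            metrics[model] = evaluate_predictions(
                yte, predict_hybrid(hybrid, Xte), labels
            )
        elif model in _BASELINE_SPEC:
            if rows_cached is None:
                rows_cached = (last20_matrix(train), last20_matrix(test))
            (Xtr_r, ytr_r, _), (Xte_r, yte_r, _) = rows_cached
            fitted = fit_baseline(Xtr_r, ytr_r, _BASELINE_SPEC[model], seed)
            metrics[model] = evaluate_predictions(
                yte_r, predict_baseline(fitted, Xte_r), labels
            )
        else:
            raise ValueError(
                f"unknown model {model!r}; expected one of {EXPERIMENT_MODELS}"
            )
    return ExperimentReport(
        dataset_variant=dataset_variant.upper(),
        split=split,
        seed=seed,
        metrics=metrics,
        config_echo={"models": list(models), "train_cfg": train_cfg.__dict__},
    )
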