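"""Deterministic feature constructions.

Three feature views of a measurement are used downstream:

* **Tensor view** — the 100x10 response matrix reshaped into a 10x10x10
  array (channels x rows x columns) for the convolutional backbone. Within
  each channel the 100 seconds are laid out row-major: element (i, j) is the
  response at t = 10*i + j + 1. The reshape is a bijection; ``flatten_tensor``
  is its exact inverse.

* **Last-20 rows** — the 10-vector of channel responses at each of the last
  20 seconds (t = 81..100), when every sensor has stabilized. These
  per-timepoint rows are the inputs of the classical baselines and of PCA,
  so one measurement contributes 20 rows.

* **PCA** — principal-component screening of last-20 rows (mean-centred,
  no column standardization), reporting loadings and explained-variance
  ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from enoseml.data import Measurement, MeasurementSet, N_CHANNELS, N_TIMEPOINTS

__all__ = [
    "TensorSample",
    "BaselineRow",
    "PCAResult",
    "to_tensor",
    "to_tensor_set",
    "flatten_tensor",
    "last20_rows",
    "last20_matrix",
    "pca_fit",
    "pca_transform",
]

TENSOR_SIDE = 10
LAST20_START = 81  # first second of the steady-state window


@dataclass
class TensorSample:
    """A measurement in the backbone's 10x10x10 input layout."""

    tensor: np.ndarray  # (10, 10, 10): channel, row, column
    label: str
    id: str


@dataclass(frozen=True)
class BaselineRow:
    """One steady-state timepoint: the 10 channel responses at second ``t``."""

    values: np.ndarray  # (10,)
    label: str
    source_id: str
    t: int


def to_tensor(m: Measurement) -> TensorSample:
    """Reshape a measurement into the backbone's 10-channel 10x10 layout."""
    if m.responses.shape != (N_TIMEPOINTS, N_CHANNELS):
        raise ValueError(
            f"expected {N_TIMEPOINTS}x{N_CHANNELS} responses, got {m.responses.shape}"
        )
    # (t, s) -> (s, i, j) with t = 10*i + j (0-based): transpose then reshape
    tensor = m.responses.T.reshape(N_CHANNELS, TENSOR_SIDE, TENSOR_SIDE)
    return TensorSample(tensor=tensor, label=m.label, id=m.id)


def flatten_tensor(sample: TensorSample) -> np.ndarray:
    """Invert :func:`to_tensor`: recover the 100x10 response matrix exactly."""
    return sample.tensor.reshape(N_CHANNELS, N_TIMEPOINTS).T


def to_tensor_set(mset: MeasurementSet) -> tuple[np.ndarray, list[str], list[str]]:
    """Tensorize a whole set.

    Returns ``(X, labels, ids)`` with ``X`` of shape (n, 10, 10, 10).
    """
    samples = [to_tensor(m) for m in mset]
    if not samples:
        return np.empty((0, N_CHANNELS, TENSOR_SIDE, TENSOR_SIDE)), [], []
    X = np.stack([s.tensor for s in samples])
    return X, [s.label for s in samples], [s.id for s in samples]


def last20_rows(m: Measurement) -> list[BaselineRow]:
    """The 20 steady-state rows of a measurement (t = 81..100, in order)."""
    return [
        BaselineRow(
            values=m.responses[t - 1].copy(), label=m.label, source_id=m.id, t=t
        )
        for t in range(LAST20_START, N_TIMEPOINTS + 1)
    ]


def last20_matrix(mset: MeasurementSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack the last-20 rows of every measurement.

    Returns ``(X, labels, source_ids)``; ``X`` has shape (20 * n, 10) and the
    label/id arrays align with its rows. Row order follows measurement order,
    then time.
    """
    n = len(mset)
    X = np.empty((20 * n, N_CHANNELS))
    labels = np.empty(20 * n, dtype=object)
    ids = np.empty(20 * n, dtype=object)
    for k, m in enumerate(mset):
        X[20 * k : 20 * (k + 1)] = m.responses[LAST20_START - 1 :]
        labels[20 * k : 20 * (k + 1)] = m.label
        ids[20 * k : 20 * (k + 1)] = m.id
    return X, labels, ids


def save_tensors(path: str | Path, X: np.ndarray, labels: list[str], ids: list[str]) -> None:
    """Serialize a tensor stack as ``.npz`` with a JSON sidecar of metadata.

    The sidecar lives at ``<path>.json`` and carries ids and labels in row
    order, so the array container stays language-portable.
    """
    path = Path(path)
    np.savez(path, tensors=np.asarray(X))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"ids": list(ids), "labels": list(labels)}))


def load_tensors(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Inverse of :func:`save_tensors`."""
    path = Path(path)
    with np.load(path) as data:
        X = data["tensors"]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if len(meta["ids"]) != len(X):
        raise ValueError(
            f"{path}: sidecar lists {len(meta['ids'])} ids for {len(X)} tensors"
        )
    return X, meta["labels"], meta["ids"]


# ---------------------------------------------------------------------------
# PCA screening
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Fitted principal components of channel-space rows."""

    component_loadings: np.ndarray  # (k, 10), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,), non-increasing
    mean: np.ndarray  # (10,)

    @property
    def cumulative_variance_ratio(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


def pca_fit(rows: np.ndarray, k: int) -> PCAResult:
    """Fit a k-component PCA on (n, 10) rows.

    Rows are mean-centred but not standardized. Rank-deficient input yields
    trailing zero explained-variance ratios rather than an error.
    """
    rows = np.asarray(rows, dtype=np.float64)
    if rows.ndim != 2:
        raise ValueError(f"rows must be 2-D, got shape {rows.shape}")
    n, p = rows.shape
    if not 1 <= k <= p:
        raise ValueError(f"k must be in 1..{p}, got {k}")
    if n <= k:
        raise ValueError(f"need more rows ({n}) than components ({k})")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(rows)
    ratio = np.clip(pca.explained_variance_ratio_, 0.0, None)
    return PCAResult(
        component_loadings=pca.components_,
        explained_variance_ratio=ratio,
        mean=pca.mean_,
    )


def pca_transform(result: PCAResult, rows: np.ndarray) -> np.ndarray:
    """Project rows onto the fitted components: ``(rows - mean) @ loadings.T``."""
    rows = np.asarray(rows, dtype=np.float64)
    return (rows - result.mean) @ result.component_loadings.T
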