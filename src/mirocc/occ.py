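"""One-class classifiers (data descriptions) for hairpin feature vectors.

A one-class classifier is trained on target-class examples only and
classifies unseen samples as *target* (accepted) or *outlier*
(rejected).  Two data descriptions are provided:

* ``gauss_dd`` — a Gaussian description: samples are scored by squared
  Mahalanobis distance to the training mean under a regularized
  covariance (sigma + lambda*I, lambda = regularization * trace(sigma)/d).
* ``knn_dd`` — a k-nearest-neighbour description: a sample's score is
  its distance to the k-th nearest stored training point (training
  scores are computed leave-one-out; prediction uses all stored points).

Features are z-scored inside the model using training-target statistics
only, so no information leaks from outliers or test folds, and the
decision is invariant to affine rescaling of any feature.  The decision
threshold is the empirical (1 - rejection_fraction) quantile of the
training scores under the nearest-rank rule: with n training scores
sorted ascending, the threshold is the ceil((1-f)*n)-th smallest, so
n - ceil((1-f)*n) training targets score beyond it (fewer under ties).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import FeatureTable, OUTLIER, TARGET

KINDS = ("gauss_dd", "knn_dd")

_MODEL_FORMAT = "mirocc-occ-model-v1"
_VAR_FLOOR = 1e-12


@dataclass
class OCCModel:
    """A fitted one-class data description plus its decision threshold."""

    kind: str
    feature_names: list[str]
    center: np.ndarray  # per-feature training mean (raw scale)
    scale: np.ndarray  # per-feature training std, floored
    threshold: float
    rejection_fraction: float
    # gauss_dd
    mean_z: np.ndarray | None = None
    precision: np.ndarray | None = None
    # knn_dd
    train_z: np.ndarray | None = None
    k_neighbors: int | None = None

    def score(self, x: np.ndarray) -> np.ndarray:
        """Outlier score per row; higher means further from the target class."""
        z = (np.asarray(x, dtype=float) - self.center) / self.scale
        if self.kind == "gauss_dd":
            d = z - self.mean_z
            return np.einsum("ij,jk,ik->i", d, self.precision, d)
        dist = cdist(z, self.train_z)
        k = min(self.k_neighbors, self.train_z.shape[0])
        return np.sort(dist, axis=1)[:, k - 1]


def _nearest_rank_threshold(scores: np.ndarray, rejection_fraction: float) -> float:
    n = scores.size
    rank = math.ceil((1.0 - rejection_fraction) * n)
    rank = min(max(rank, 1), n)
    return float(np.sort(scores)[rank - 1])


def fit_occ(
    table: FeatureTable,
    kind: str = "gauss_dd",
    rejection_fraction: float = 0.05,
    regularization: float = 1e-3,
    k_neighbors: int = 5,
    seed: int = 0,
) -> OCCModel:
    """Fit a data description on the table's target rows.

    The table should already be restricted to the selected features.
    ``seed`` is accepted for interface uniformity; both descriptions are
    deterministic given the data.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown OCC kind {kind!r}; choose from {KINDS}")
    if not 0.0 < rejection_fraction < 1.0:
        raise ValueError("rejection_fraction must be in (0, 1)")
    rows = np.flatnonzero(table.label_mask(TARGET))
    if rows.size < 5:
        raise ValueError(f"need >= 5 target rows to fit, got {rows.size}")
    x = table.values[rows]
    center = x.mean(axis=0)
    scale = np.sqrt(np.maximum(x.var(axis=0), _VAR_FLOOR))
    z = (x - center) / scale

    if kind == "gauss_dd":
        mean_z = z.mean(axis=0)
        d = z.shape[1]
        sigma = np.cov(z, rowvar=False, ddof=1).reshape(d, d)
        lam = regularization * np.trace(sigma) / d
        if lam <= 0:
            lam = regularization
        precision = np.linalg.inv(sigma + lam * np.eye(d))
        diff = z - mean_z
        train_scores = np.einsum("ij,jk,ik->i", diff, precision, diff)
        model = OCCModel(
            kind=kind,
            feature_names=list(table.feature_names),
            center=center,
            scale=scale,
            threshold=0.0,
            rejection_fraction=rejection_fraction,
            mean_z=mean_z,
            precision=precision,
        )
    else:
        k = min(k_neighbors, z.shape[0] - 1)
        dist = cdist(z, z)
        # leave-one-out: column 0 of the sorted row is the self-distance
        train_scores = np.sort(dist, axis=1)[:, k]
        model = OCCModel(
            kind=kind,
            feature_names=list(table.feature_names),
            center=center,
            scale=scale,
            threshold=0.0,
            rejection_fraction=rejection_fraction,
            train_z=z,
            k_neighbors=k,
        )
    model.threshold = _nearest_rank_threshold(train_scores, rejection_fraction)
    return model


def predict_occ(model: OCCModel, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Classify each sample: ``target`` iff score <= threshold.

    Returns (labels, scores).  The table may carry extra feature
    columns; the model's features must all be present.
    """
    missing = [f for f in model.feature_names if f not in table.feature_names]
    if missing:
        raise KeyError(f"table is missing model features: {missing}")
    sub = table.subset_features(model.feature_names)
    scores = model.score(sub.values)
    labels = np.where(scores <= model.threshold, TARGET, OUTLIER).astype(object)
    return labels, scores


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_occ(model: OCCModel, path) -> None:
    """Serialize a model to a self-describing JSON file."""
    payload = {
        "format": _MODEL_FORMAT,
        "kind": model.kind,
        "feature_names": model.feature_names,
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "threshold": model.threshold,
        "rejection_fraction": model.rejection_fraction,
    }
    if model.kind == "gauss_dd":
        payload["mean_z"] = model.mean_z.tolist()
        payload["precision"] = model.precision.tolist()
    else:
        payload["train_z"] = model.train_z.tolist()
        payload["k_neighbors"] = model.k_neighbors
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_occ(path) -> OCCModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a mirocc OCC model file")
    common = dict(
        kind=payload["kind"],
        feature_names=list(payload["feature_names"]),
        center=np.asarray(payload["center"], dtype=float),
        scale=np.asarray(payload["scale"], dtype=float),
        threshold=float(payload["threshold"]),
        rejection_fraction=float(payload["rejection_fraction"]),
    )
    if payload["kind"] == "gauss_dd":
        return OCCModel(
            **common,
            mean_z=np.asarray(payload["mean_z"], dtype=float),
            precision=np.asarray(payload["precision"], dtype=float),
        )
    return OCCModel(
        **common,
        train_z=np.asarray(payload["train_z"], dtype=float),
        k_neighbors=int(payload["k_neighbors"]),
    )
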