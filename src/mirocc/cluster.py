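"""Feature clustering for redundancy-aware selection.

Features are clustered as points: each feature is represented by its
value vector across the *positive (target) samples only*, z-scored, and
k-means (k-means++ initialization, Lloyd iterations) groups features
whose vectors are similar.  This drives the cluster-based selectors
(RFC, SFC, HIC), which draw representatives from clusters instead of
from the raw ranking to avoid over-representing redundant features.

Two distances are offered.  The default ``euclidean`` distance on
z-scored vectors mirrors the classic setup — and inherits its known
flaw: a feature and its negation (e.g. %A vs %G in near-binary
composition data) are maximally distant even though they carry the same
information.  The ``abs_correlation`` mode repairs this by embedding
features so that squared k-means distance equals 2(1 - r²), a monotone
function of 1 - |Pearson r|; a feature and its sign-flip are then at
distance zero and always co-cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .io_formats import FeatureTable, TARGET

DISTANCES = ("euclidean", "abs_correlation")


@dataclass(frozen=True)
class ClusterAssignment:
    """feature name -> cluster id, with the parameters that produced it."""

    assignment: dict[str, int]
    k: int
    k_effective: int
    seed: int
    distance: str

    def members(self) -> dict[int, list[str]]:
        """cluster id -> member feature names (sorted)."""
        out: dict[int, list[str]] = {}
        for name in sorted(self.assignment):
            out.setdefault(self.assignment[name], []).append(name)
        return out


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    z = np.zeros_like(x)
    ok = std > 0
    z[:, ok] = (x[:, ok] - mean[ok]) / std[ok]
    return z


def _abs_correlation_embedding(points: np.ndarray) -> np.ndarray:
    """Embed feature vectors so squared distance = 2(1 - r^2).

    Rows are feature vectors (already z-scored across target samples).
    The Gram matrix of the embedding is the elementwise square of the
    correlation matrix, which is positive semidefinite, so an exact
    finite-dimensional embedding exists via its eigendecomposition.
    """
    norms = np.linalg.norm(points, axis=1)
    unit = np.zeros_like(points)
    ok = norms > 0
    unit[ok] = points[ok] / norms[ok, None]
    gram = (unit @ unit.T) ** 2
    np.fill_diagonal(gram, 1.0)
    w, v = np.linalg.eigh(gram)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def cluster_features(
    table: FeatureTable,
    k: int = 100,
    seed: int = 0,
    distance: str = "euclidean",
) -> ClusterAssignment:
    """Cluster features by their value vectors over target samples.

    Features are sorted by name before clustering so the seeded result
    is independent of the table's column order.  ``k_effective`` is
    min(k, n_features); cluster ids are compacted to 0..k_effective-1 in
    order of first appearance.
    """
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}; choose from {DISTANCES}")
    if k < 1:
        raise ValueError("k must be >= 1")
    target_rows = np.flatnonzero(table.label_mask(TARGET))
    if target_rows.size == 0:
        raise ValueError("no target rows to cluster on")

    names = sorted(table.feature_names)
    col_idx = [table.feature_names.index(n) for n in names]
    x = table.values[np.ix_(target_rows, col_idx)]
    z = _zscore_columns(x)
    points = z.T  # one row per feature

    k_eff = min(k, len(names))
    if k_eff == len(names):
        raw = np.arange(len(names))
    elif distance == "abs_correlation":
        emb = _abs_correlation_embedding(points)
        raw = KMeans(
            n_clusters=k_eff, init="k-means++", n_init=1, tol=1e-6,
            max_iter=300, algorithm="lloyd", random_state=seed,
        ).fit_predict(emb)
    else:
        raw = KMeans(
            n_clusters=k_eff, init="k-means++", n_init=1, tol=1e-6,
            max_iter=300, algorithm="lloyd", random_state=seed,
        ).fit_predict(points)

    # compact ids in order of first appearance over name-sorted features
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for name, cid in zip(names, raw):
        if cid not in remap:
            remap[cid] = len(remap)
        assignment[name] = remap[cid]
    return ClusterAssignment(
        assignment=assignment,
        k=k,
        k_effective=len(remap),
        seed=seed,
        distance=distance,
    )
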