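"""Supervised discretization and information-gain feature scoring.

Information gain of a feature is the reduction in class-label entropy
(target vs outlier, base-2) achieved by conditioning on the discretized
feature:

    IG = H(labels) - sum_b p(b) * H(labels | bin b)

Continuous features are discretized first; the default scheme places bin
edges at empirical quantiles (equal-frequency binning), which makes the
score invariant under strictly monotone transforms of the feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import FeatureTable, OUTLIER, TARGET

SCHEMES = ("equal_frequency", "equal_width")


@dataclass(frozen=True)
class IGScore:
    """Information gain (bits) of one feature at a given bin count."""

    feature_name: str
    gain: float
    bins: int


def discretize(values, n_bins: int = 10, scheme: str = "equal_frequency") -> np.ndarray:
    """Map a numeric vector to integer bin indices.

    Equal-frequency edges sit at empirical quantiles; identical edges are
    merged, so heavily tied data may occupy fewer effective bins.  A
    constant vector lands in a single bin.
    """
    v = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if v.size == 0 or np.all(v == v[0]):
        return np.zeros(v.size, dtype=int)
    if scheme == "equal_frequency":
        edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
        edges = np.unique(edges)
    elif scheme == "equal_width":
        edges = np.linspace(v.min(), v.max(), n_bins + 1)[1:-1]
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    # value <= edge falls in the lower bin
    return np.searchsorted(edges, v, side="left").astype(int)


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def label_entropy(labels) -> float:
    labels = np.asarray(labels, dtype=object)
    _, counts = np.unique(labels.astype(str), return_counts=True)
    return _entropy(counts)


def information_gain(
    feature,
    labels,
    n_bins: int = 10,
    scheme: str = "equal_frequency",
    feature_name: str = "",
) -> IGScore:
    """Information gain of one feature against the target/outlier labels."""
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if feature.shape[0] != labels.shape[0]:
        raise ValueError("feature and labels lengths differ")
    classes = set(labels)
    if not {TARGET, OUTLIER} <= classes:
        raise ValueError("information gain undefined: need both target and outlier labels")
    bins = discretize(feature, n_bins=n_bins, scheme=scheme)
    y = (labels == TARGET).astype(int)
    h_labels = _entropy(np.bincount(y))
    n = len(y)
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += mask.sum() / n * _entropy(np.bincount(y[mask]))
    gain = max(h_labels - cond, 0.0)
    return IGScore(feature_name=feature_name, gain=gain, bins=n_bins)


def rank_by_gain(
    table: FeatureTable, n_bins: int = 10, scheme: str = "equal_frequency"
) -> list[IGScore]:
    """All features scored and sorted by descending gain.

    Ties are broken by descending variance, then ascending feature name,
    so the ranking is fully deterministic.
    """
    scores = []
    variances = {}
    for j, name in enumerate(table.feature_names):
        col = table.values[:, j]
        scores.append(
            information_gain(col, table.labels, n_bins=n_bins, scheme=scheme, feature_name=name)
        )
        variances[name] = float(np.var(col))
    scores.sort(key=lambda s: (-s.gain, -variances[s.feature_name], s.feature_name))
    return scores
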