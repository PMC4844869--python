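"""The eight feature-selection strategies, plus the cross-dataset combiner.

Each strategy reduces a labeled feature table to an ordered set of
``n`` features (default 50).  Four are designed to help and four to
probe (controls):

* **HIG** — highest information gain (supervised filter).
* **LIG** — lowest information gain (negative control).
* **RFS** — uniform random features (random control).
* **RFC** — one random feature per k-means feature cluster, then a
  random subset (redundancy-aware control).
* **SFC** — all features from up to three randomly visited clusters
  (tests the impact of concentrated redundancy).
* **HIC** — highest-gain feature per cluster, re-ranked by gain.
* **ZNF** — zero-norm filter: rank by the number of nonzero values over
  positive samples, after dropping all-zero and below-threshold features.
* **PCF** — Pearson-correlation filter on positive samples only: greedy
  min-max-|r| construction preferring mutually uncorrelated features.

:func:`combine_selections` builds the cross-dataset "combined" set: the
``n`` features most commonly present among each dataset's first
``candidate_size`` (default 100) selected features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterAssignment, cluster_features
from .infogain import information_gain, rank_by_gain
from .io_formats import FeatureTable, TARGET

METHODS = ("LIG", "RFS", "RFC", "SFC", "HIG", "HIC", "ZNF", "PCF", "COMB")

_GAIN_EPS = 1e-12


@dataclass(frozen=True)
class SelectionResult:
    """Ordered selected feature names with method/seed provenance."""

    method: str
    selected: tuple[str, ...] | list[str]
    scores: dict[str, float] | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)
    n_requested: int = 50
    shortfall: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "selected", tuple(self.selected))
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate features in selection")


def _variances(table: FeatureTable) -> dict[str, float]:
    var = np.var(table.values, axis=0)
    return {name: float(v) for name, v in zip(table.feature_names, var)}


def _target_matrix(table: FeatureTable) -> np.ndarray:
    rows = np.flatnonzero(table.label_mask(TARGET))
    if rows.size == 0:
        raise ValueError("table has no target rows")
    return table.values[rows]


# ---------------------------------------------------------------------------
# Zero-norm (ZNF)
# ---------------------------------------------------------------------------


def zero_norm_count(values, tolerance: float = 0.0) -> int:
    """Number of entries whose magnitude exceeds ``tolerance``."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return int(np.sum(np.abs(v) > tolerance))


def select_znf(
    table: FeatureTable,
    n: int = 50,
    threshold: int = 1,
    tolerance: float = 0.0,
    seed: int = 0,
) -> SelectionResult:
    """Zero-norm selection over positive samples.

    Features whose target-row vector is entirely zero are removed, then
    features with fewer than ``threshold`` nonzero values; survivors are
    ranked by descending nonzero count (ties: descending variance, then
    name) and the top ``n`` kept.
    """
    x = _target_matrix(table)
    variances = _variances(table)
    counts = {
        name: zero_norm_count(x[:, j], tolerance=tolerance)
        for j, name in enumerate(table.feature_names)
    }
    survivors = [f for f, c in counts.items() if c > 0 and c >= threshold]
    survivors.sort(key=lambda f: (-counts[f], -variances[f], f))
    selected = survivors[:n]
    return SelectionResult(
        method="ZNF",
        selected=selected,
        scores={f: float(counts[f]) for f in selected},
        seed=seed,
        params={"threshold": threshold, "tolerance": tolerance},
        n_requested=n,
        shortfall=len(selected) == 0,
    )


# ---------------------------------------------------------------------------
# Information-gain selectors (HIG, LIG)
# ---------------------------------------------------------------------------


def select_hig(
    table: FeatureTable,
    n: int = 50,
    n_bins: int = 10,
    scheme: str = "equal_frequency",
    seed: int = 0,
) -> SelectionResult:
    """Top ``n`` features by information gain."""
    ranking = rank_by_gain(table, n_bins=n_bins, scheme=scheme)
    top = ranking[:n]
    return SelectionResult(
        method="HIG",
        selected=[s.feature_name for s in top],
        scores={s.feature_name: s.gain for s in top},
        seed=seed,
        params={"n_bins": n_bins, "scheme": scheme},
        n_requested=n,
    )


def select_lig(
    table: FeatureTable,
    n: int = 50,
    n_bins: int = 10,
    scheme: str = "equal_frequency",
    bin_step: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Bottom ``n`` features by information gain, via bin escalation.

    With coarse binning many features score (numerically) zero gain and
    cannot be ordered.  The procedure keeps only the zero-gain pool and
    recomputes gain with progressively more bins (step ``bin_step``,
    capped at n_samples // 2), letting finer discretization split the
    pool, until at most ``n`` zero-gain features remain or the cap is
    hit.  The final set is padded to ``n`` with the lowest-gain features
    of the current pool and ordered by ascending gain (ties: ascending
    variance, then name).
    """
    variances = _variances(table)
    pool = list(table.feature_names)
    cap = max(n_bins, table.n_samples // 2)
    bins = n_bins

    def gains_for(pool_names: list[str], b: int) -> dict[str, float]:
        out = {}
        for name in pool_names:
            col = table.column(name)
            out[name] = information_gain(
                col, table.labels, n_bins=b, scheme=scheme, feature_name=name
            ).gain
        return out

    while True:
        gains = gains_for(pool, bins)
        zero_pool = [f for f in pool if gains[f] <= _GAIN_EPS]
        if len(zero_pool) <= n or bins >= cap:
            order = sorted(pool, key=lambda f: (gains[f], variances[f], f))
            selected = order[:n]
            break
        pool = zero_pool
        bins = min(bins + bin_step, cap)

    return SelectionResult(
        method="LIG",
        selected=selected,
        scores={f: gains[f] for f in selected},
        seed=seed,
        params={"n_bins": n_bins, "scheme": scheme, "final_bins": bins},
        n_requested=n,
    )


# ---------------------------------------------------------------------------
# Random selectors (RFS) and cluster-based selectors (RFC, SFC, HIC)
# ---------------------------------------------------------------------------


def select_rfs(table: FeatureTable, n: int = 50, seed: int = 0) -> SelectionResult:
    """Uniform random sample of features, without replacement."""
    rng = np.random.default_rng(seed)
    names = sorted(table.feature_names)
    size = min(n, len(names))
    picked = rng.choice(len(names), size=size, replace=False)
    return SelectionResult(
        method="RFS",
        selected=[names[i] for i in picked],
        seed=seed,
        params={},
        n_requested=n,
    )


def _clusters(table, k, seed, distance) -> ClusterAssignment:
    return cluster_features(table, k=k, seed=seed, distance=distance)


def select_rfc(
    table: FeatureTable,
    n: int = 50,
    k: int = 100,
    seed: int = 0,
    distance: str = "euclidean",
) -> SelectionResult:
    """One random representative per feature cluster, then ``n`` at random."""
    rng = np.random.default_rng(seed)
    ca = _clusters(table, k, seed, distance)
    reps = []
    for cid, members in sorted(ca.members().items()):
        reps.append(members[rng.integers(len(members))])
    size = min(n, len(reps))
    picked = rng.choice(len(reps), size=size, replace=False)
    return SelectionResult(
        method="RFC",
        selected=[reps[i] for i in picked],
        seed=seed,
        params={"k": k, "distance": distance},
        n_requested=n,
    )


def select_hic(
    table: FeatureTable,
    n: int = 50,
    k: int = 100,
    n_bins: int = 10,
    scheme: str = "equal_frequency",
    seed: int = 0,
    distance: str = "euclidean",
) -> SelectionResult:
    """Highest-gain feature per cluster, re-ranked by gain, top ``n``."""
    ca = _clusters(table, k, seed, distance)
    variances = _variances(table)
    gains = {
        s.feature_name: s.gain
        for s in rank_by_gain(table, n_bins=n_bins, scheme=scheme)
    }
    reps = []
    for cid, members in sorted(ca.members().items()):
        best = min(members, key=lambda f: (-gains[f], -variances[f], f))
        reps.append(best)
    reps.sort(key=lambda f: (-gains[f], -variances[f], f))
    selected = reps[:n]
    return SelectionResult(
        method="HIC",
        selected=selected,
        scores={f: gains[f] for f in selected},
        seed=seed,
        params={"k": k, "n_bins": n_bins, "scheme": scheme, "distance": distance},
        n_requested=n,
    )


def select_sfc(
    table: FeatureTable,
    n: int = 50,
    k: int = 100,
    max_clusters: int = 3,
    seed: int = 0,
    distance: str = "euclidean",
) -> SelectionResult:
    """All features from up to ``max_clusters`` randomly visited clusters.

    Clusters are visited in seeded random order; member features
    accumulate until ``n`` are reached or ``max_clusters`` clusters have
    been visited.  An over-full accumulation is truncated to ``n`` by a
    seeded uniform subsample; a shortfall is flagged, not an error.
    """
    rng = np.random.default_rng(seed)
    ca = _clusters(table, k, seed, distance)
    members = ca.members()
    order = rng.permutation(sorted(members))
    accumulated: list[str] = []
    visited = 0
    for cid in order:
        if visited >= max_clusters or len(accumulated) >= n:
            break
        accumulated.extend(members[int(cid)])
        visited += 1
    if len(accumulated) > n:
        picked = rng.choice(len(accumulated), size=n, replace=False)
        selected = [accumulated[i] for i in sorted(picked)]
    else:
        selected = accumulated
    return SelectionResult(
        method="SFC",
        selected=selected,
        seed=seed,
        params={"k": k, "max_clusters": max_clusters, "distance": distance},
        n_requested=n,
        shortfall=len(selected) < min(n, table.n_features),
    )


# ---------------------------------------------------------------------------
# Pearson-correlation selection (PCF)
# ---------------------------------------------------------------------------


def select_pcf(table: FeatureTable, n: int = 50, seed: int = 0) -> SelectionResult:
    """Greedy min-max-|r| selection on positive samples only.

    The set is seeded with the feature of minimal mean |r| to all
    others; each step adds the candidate minimizing the maximum |r| to
    the current set (ties: smaller mean |r|, then name).  Constant
    features are assigned correlation 0 by convention.
    """
    x = _target_matrix(table)
    if x.shape[0] < 2:
        raise ValueError("PCF needs >= 2 target rows (correlation undefined)")
    names = list(table.feature_names)
    d = len(names)
    std = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.atleast_2d(c)
    const = std == 0
    c[const, :] = 0.0
    c[:, const] = 0.0
    np.fill_diagonal(c, 1.0)
    absc = np.abs(c)
    mean_r = (absc.sum(axis=0) - 1.0) / max(d - 1, 1)

    first = min(range(d), key=lambda j: (mean_r[j], names[j]))
    chosen = [first]
    remaining = set(range(d)) - {first}
    while len(chosen) < min(n, d):
        best = min(
            remaining,
            key=lambda j: (absc[j, chosen].max(), mean_r[j], names[j]),
        )
        chosen.append(best)
        remaining.discard(best)
    return SelectionResult(
        method="PCF",
        selected=[names[j] for j in chosen],
        scores={names[j]: float(mean_r[j]) for j in chosen},
        seed=seed,
        params={},
        n_requested=n,
    )


# ---------------------------------------------------------------------------
# Cross-dataset combination (COMB)
# ---------------------------------------------------------------------------


def combine_selections(
    per_dataset_results: list[SelectionResult],
    n: int = 50,
    candidate_size: int = 100,
) -> SelectionResult:
    """The ``n`` features most commonly selected across datasets.

    Each input should be that dataset's selection re-run with
    ``n_requested=candidate_size`` (default 100); only its first
    ``candidate_size`` features are tallied.  Ranking is by frequency
    (descending), then mean within-dataset rank (ascending), then name.
    """
    if len(per_dataset_results) < 2:
        raise ValueError("combine needs >= 2 per-dataset selections")
    methods = {r.method for r in per_dataset_results}
    if len(methods) != 1:
        raise ValueError(f"mixed methods cannot be combined: {sorted(methods)}")
    freq: dict[str, int] = {}
    ranks: dict[str, list[int]] = {}
    for res in per_dataset_results:
        head = list(res.selected)[: min(candidate_size, len(res.selected))]
        for rank, name in enumerate(head, start=1):
            freq[name] = freq.get(name, 0) + 1
            ranks.setdefault(name, []).append(rank)
    order = sorted(
        freq, key=lambda f: (-freq[f], float(np.mean(ranks[f])), f)
    )
    selected = order[:n]
    return SelectionResult(
        method="COMB",
        selected=selected,
        scores={f: float(freq[f]) for f in selected},
        seed=per_dataset_results[0].seed,
        params={
            "base_method": per_dataset_results[0].method,
            "candidate_size": candidate_size,
            "n_datasets": len(per_dataset_results),
        },
        n_requested=n,
    )


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

_DISPATCH = {
    "HIG": select_hig,
    "LIG": select_lig,
    "RFS": select_rfs,
    "RFC": select_rfc,
    "SFC": select_sfc,
    "HIC": select_hic,
    "ZNF": select_znf,
    "PCF": select_pcf,
}


def select_features(
    table: FeatureTable, method: str, n: int = 50, seed: int = 0, **params
) -> SelectionResult:
    """Run one named selection strategy on a labeled feature table."""
    key = method.upper()
    if key not in _DISPATCH:
        raise ValueError(f"unknown selection method {method!r}")
    return _DISPATCH[key](table, n=n, seed=seed, **params)
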