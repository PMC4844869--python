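"""Seeded generators for benchmark data.

Two generators make every stage of the workbench testable without any
external download:

* :func:`gen_feature_table` — a feature table with planted statistical
  structure emulating a hairpin feature matrix: a target class and an
  outlier pool, class-informative features (mean shift ``delta`` for
  targets), correlated redundant feature clusters (pairwise correlation
  ``rho``, with alternating members sign-flipped to emulate
  anticorrelated-but-logically-identical composition features), sparse
  features (zeros with probability ``sparse_p``) and pure-noise
  features.  Feature names carry their ground-truth group (``inf_``,
  ``red_``, ``sparse_``, ``noise_``), so selector-recovery assertions
  read straight off the names.

* :func:`gen_hairpins` — toy RNA hairpins (random 5' arm, loop, reverse
  complement 3' arm with per-base mismatches, construction-derived
  structure) and pseudo hairpins (same length and composition model but
  independent arms, structure from the maxpair folder), emulating true
  pre-miRNA precursors vs genomic pseudo hairpins.

The default table dimensions follow the study conditions the workbench
targets: a few hundred positives against a 980-strong pseudo-hairpin
outlier pool and a ~700-column feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featurize import maxpair_fold
from .io_formats import FeatureTable, HairpinRecord, OUTLIER, TARGET
from .select import SelectionResult

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = "ACGU"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure feature-table generator."""

    n_target: int = 200
    n_outlier: int = 980
    n_informative: int = 10
    delta: float = 2.0
    n_redundant_clusters: int = 20
    cluster_size: int = 5
    rho: float = 0.9
    n_sparse: int = 50
    sparse_p: float = 0.8
    n_noise: int = 540
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_target, self.n_outlier, self.n_informative,
            self.n_redundant_clusters, self.cluster_size, self.n_sparse,
            self.n_noise,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 <= self.sparse_p <= 1.0:
            raise ValueError("sparse_p must be in [0, 1]")

    @property
    def n_features(self) -> int:
        return (
            self.n_informative
            + self.n_redundant_clusters * self.cluster_size
            + self.n_sparse
            + self.n_noise
        )


def gen_feature_table(spec: SyntheticSpec) -> FeatureTable:
    """A labeled feature table with the planted structure of ``spec``."""
    if spec.n_features == 0:
        raise ValueError("spec yields zero features")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_target + spec.n_outlier
    is_target = np.arange(n) < spec.n_target

    blocks: list[np.ndarray] = []
    names: list[str] = []

    # informative: N(delta, 1) for targets, N(0, 1) for outliers
    if spec.n_informative:
        x = rng.standard_normal((n, spec.n_informative))
        x[is_target] += spec.delta
        blocks.append(x)
        names += [f"inf_{i:02d}" for i in range(spec.n_informative)]

    # redundant clusters: shared latent + independent noise, pairwise corr rho;
    # odd members sign-flipped (anticorrelated vectors, same information)
    for c in range(spec.n_redundant_clusters):
        latent = rng.standard_normal(n)
        a, b = np.sqrt(spec.rho), np.sqrt(1.0 - spec.rho)
        for j in range(spec.cluster_size):
            member = a * latent + b * rng.standard_normal(n)
            if j % 2 == 1:
                member = -member
            blocks.append(member[:, None])
            names.append(f"red_{c:02d}_{j}")

    # sparse: zero with probability p, else |N(0,1)|
    if spec.n_sparse:
        mag = np.abs(rng.standard_normal((n, spec.n_sparse)))
        mask = rng.random((n, spec.n_sparse)) < spec.sparse_p
        mag[mask] = 0.0
        blocks.append(mag)
        names += [f"sparse_{i:02d}" for i in range(spec.n_sparse)]

    # pure noise: N(0, 1) for both classes
    if spec.n_noise:
        blocks.append(rng.standard_normal((n, spec.n_noise)))
        names += [f"noise_{i:03d}" for i in range(spec.n_noise)]

    values = np.hstack(blocks)
    labels = np.where(is_target, TARGET, OUTLIER).astype(object)
    sample_ids = [
        f"t{i:04d}" if is_target[i] else f"o{i - spec.n_target:04d}" for i in range(n)
    ]
    return FeatureTable(
        sample_ids=sample_ids, feature_names=names, values=values, labels=labels
    )


def informative_recovery(selection: SelectionResult) -> float:
    """Fraction of selected features that are planted informative ones."""
    if not selection.selected:
        return 0.0
    hits = sum(1 for f in selection.selected if f.startswith("inf_"))
    return hits / len(selection.selected)


# ---------------------------------------------------------------------------
# Toy hairpins
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def gen_hairpins(
    n: int,
    stem_len: int = 20,
    loop_len: int = 6,
    mismatch_rate: float = 0.1,
    klass: str = "hairpin",
    seed: int = 0,
) -> list[HairpinRecord]:
    """Generate toy hairpin or pseudo-hairpin records with structures.

    ``hairpin``: a random 5' arm, a loop, and the arm's reverse
    complement with per-base mismatch probability ``mismatch_rate``
    (mismatched bases cannot pair, not even as GU wobble); the structure
    string follows from the construction.  ``pseudo``: the same length
    and base-composition model but the two arms drawn independently, so
    complementarity is at chance; the structure comes from the maxpair
    folder.
    """
    if stem_len < 4:
        raise ValueError("stem_len must be >= 4")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if klass not in ("hairpin", "pseudo"):
        raise ValueError(f"unknown class {klass!r}")
    rng = np.random.default_rng(seed)
    records: list[HairpinRecord] = []
    for idx in range(n):
        if klass == "hairpin":
            arm5 = _random_seq(rng, stem_len)
            arm3 = [_COMPLEMENT[b] for b in reversed(arm5)]
            matched = [True] * stem_len  # index into arm3 positions
            for j in range(stem_len):
                if rng.random() < mismatch_rate:
                    partner = arm5[stem_len - 1 - j]
                    # any base that neither Watson-Crick- nor wobble-pairs
                    choices = [
                        b
                        for b in _BASES
                        if (partner, b) not in (
                            ("A", "U"), ("U", "A"), ("G", "C"),
                            ("C", "G"), ("G", "U"), ("U", "G"),
                        )
                    ]
                    arm3[j] = choices[rng.integers(len(choices))]
                    matched[j] = False
            seq = arm5 + _random_seq(rng, loop_len) + "".join(arm3)
            struct = (
                "".join("(" if matched[stem_len - 1 - i] else "." for i in range(stem_len))
                + "." * loop_len
                + "".join(")" if matched[j] else "." for j in range(stem_len))
            )
            records.append(
                HairpinRecord(id=f"hairpin_{idx:04d}", sequence=seq, structure=struct)
            )
        else:
            seq = _random_seq(rng, 2 * stem_len + loop_len)
            struct = maxpair_fold(seq).structure
            records.append(
                HairpinRecord(id=f"pseudo_{idx:04d}", sequence=seq, structure=struct)
            )
    return records
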