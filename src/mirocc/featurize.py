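"""Hairpin feature extraction.

Computes a documented, versioned catalog of pre-miRNA hairpin features
from :class:`~mirocc.io_formats.HairpinRecord` objects.  The catalog
covers the classic feature families used in hairpin classification:

* **composition** — length, %G+C, the 4 mononucleotide and 16
  overlapping-dinucleotide frequencies;
* **triplet** — the 32 triplet structure-sequence elements (middle
  nucleotide x paired/unpaired status of the position and both
  neighbours), normalized by the number of interior positions;
* **structural** — base-pair counts, loop and stem statistics, and the
  pair-composition fractions read off the dot-bracket structure;
* **energy** — MFE, MFE/length and MFEI1, available only from an
  energy-capable fold backend.

Secondary structure comes from a pluggable backend: ``provided`` passes
through a structure already attached to the record, ``maxpair`` runs a
deterministic maximum base-pairing dynamic program (Nussinov-style, no
thermodynamics), and ``rnafold`` shells out to ViennaRNA's RNAfold for a
minimum-free-energy structure with an energy value.
"""

from __future__ import annotations

import hashlib
import shutil
import subprocess
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io_formats import FeatureTable, HairpinRecord, UNLABELED, _check_structure

BASES = "ACGU"
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)
MIN_LOOP = 3  # minimum hairpin loop size: i and j can pair only if j - i > 3

BACKENDS = ("provided", "maxpair", "rnafold")
ENERGY_BACKENDS = frozenset(["rnafold"])


# ---------------------------------------------------------------------------
# Fold backends
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldResult:
    """A secondary structure for one record, with an optional energy."""

    structure: str
    pair_count: int
    energy: float | None = None

    def __post_init__(self) -> None:
        if self.pair_count != self.structure.count("("):
            raise ValueError("pair_count does not match structure")


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def _maxpair_table(seq: str) -> list[list[int]]:
    n = len(seq)
    m = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1][j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if _can_pair(seq[i], seq[k]):
                    left = m[i + 1][k - 1]
                    right = m[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            m[i][j] = best
    return m


def _maxpair_traceback(seq: str, m: list[list[int]]) -> str:
    n = len(seq)
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        score = m[i][j]
        if score == 0:
            continue
        # Prefer pairing position i (with j first, then smaller partners),
        # falling back to leaving i unpaired.  Deterministic by construction.
        paired = False
        if _can_pair(seq[i], seq[j]) and score == 1 + m[i + 1][j - 1]:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
            paired = True
        else:
            for k in range(i + MIN_LOOP + 1, j):
                right = m[k + 1][j] if k + 1 <= j else 0
                if _can_pair(seq[i], seq[k]) and score == 1 + m[i + 1][k - 1] + right:
                    structure[i], structure[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return "".join(structure)


def maxpair_fold(sequence: str) -> FoldResult:
    """Maximum base-pairing structure by dynamic programming.

    Allowed pairs are the Watson-Crick pairs plus GU wobble; the hairpin
    loop must span at least 3 unpaired bases.  Ties are broken
    deterministically (pairing preferred over bifurcation, smaller 5'
    index first), so the structure — not just the pair count — is
    reproducible.
    """
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    m = _maxpair_table(sequence)
    structure = _maxpair_traceback(sequence, m)
    return FoldResult(structure=structure, pair_count=structure.count("("))


def _rnafold(sequence: str) -> FoldResult:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold executable not found; energy backend unavailable")
    proc = subprocess.run(
        [exe, "--noPS"],
        input=f">q\n{sequence}\n",
        capture_output=True,
        text=True,
        check=True,
    )
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    struct_line = lines[-1]
    structure = struct_line.split(None, 1)[0]
    energy = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return FoldResult(structure=structure, pair_count=structure.count("("), energy=energy)


def fold(record: HairpinRecord, backend: str = "maxpair") -> FoldResult:
    """Obtain a secondary structure for one record from the chosen backend."""
    if backend == "provided":
        if record.structure is None:
            raise ValueError(f"record {record.id!r} carries no structure")
        return FoldResult(
            structure=record.structure, pair_count=record.structure.count("(")
        )
    if backend == "maxpair":
        return maxpair_fold(record.sequence)
    if backend == "rnafold":
        result = _rnafold(record.sequence)
        _check_structure(result.structure, len(record.sequence), record.id)
        return result
    raise ValueError(f"unknown fold backend {backend!r}; choose from {BACKENDS}")


# ---------------------------------------------------------------------------
# Feature groups
# ---------------------------------------------------------------------------

DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)
# triplet status strings: '(' = paired, '.' = unpaired, for (i-1, i, i+1)
TRIPLET_STATUSES = tuple(
    a + b + c for a in ".(" for b in ".(" for c in ".("
)


def composition_features(record: HairpinRecord) -> dict[str, float]:
    """Length, %G+C and mono-/dinucleotide frequencies.

    Dinucleotides are counted over the L-1 overlapping windows and
    normalized by L-1; a length-1 sequence has all dinucleotide
    frequencies 0.
    """
    seq = record.sequence
    length = len(seq)
    out: dict[str, float] = {"length": float(length)}
    out["gc_content"] = (seq.count("G") + seq.count("C")) / length
    for b in BASES:
        out[f"freq_{b}"] = seq.count(b) / length
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(length - 1):
        counts[seq[i : i + 2]] += 1
    denom = max(length - 1, 1)
    for dn in DINUCLEOTIDES:
        out[f"freq_{dn}"] = counts[dn] / denom
    return out


def triplet_features(record: HairpinRecord, fold_result: FoldResult) -> dict[str, float]:
    """The 32 triplet structure-sequence elements.

    For each interior position i (2..L-1) the descriptor combines the
    middle nucleotide with the paired/unpaired status of positions
    i-1, i, i+1; both bracket orientations count as paired.  Counts are
    normalized by L-2, so the 32 values sum to 1 whenever L > 2.
    """
    seq = record.sequence
    struct = fold_result.structure
    length = len(seq)
    names = [f"triplet_{b}_{s}" for b in BASES for s in TRIPLET_STATUSES]
    out = dict.fromkeys(names, 0.0)
    if length < 3:
        return out
    paired = ["(" if ch in "()" else "." for ch in struct]
    for i in range(1, length - 1):
        status = paired[i - 1] + paired[i] + paired[i + 1]
        out[f"triplet_{seq[i]}_{status}"] += 1.0
    for name in names:
        out[name] /= length - 2
    return out


def _pair_list(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    return sorted(pairs)


def _runs(chars: str, target: str) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of `target` in `chars`."""
    runs = []
    start = None
    for i, ch in enumerate(chars + "\x00"):
        if ch == target and start is None:
            start = i
        elif ch != target and start is not None:
            runs.append((start, i - start))
            start = None
    return runs


def structural_features(
    record: HairpinRecord, fold_result: FoldResult
) -> dict[str, float]:
    """Counts and ratios read off the dot-bracket structure.

    Loops are maximal runs of unpaired bases immediately enclosed by a
    base pair (hairpin loops); stems are maximal runs of consecutive
    nested pairs (i,j), (i+1,j-1), ...  When the fold backend supplies an
    energy, the MFE trio is emitted as well, with
    MFEI1 = (MFE / length * 100) / %GC (GC on the 0-100 scale).
    """
    struct = fold_result.structure
    seq = record.sequence
    length = len(seq)
    pairs = _pair_list(struct)
    n_pairs = len(pairs)

    # hairpin loops: dot runs with '(' on the left and ')' on the right
    dot_runs = _runs(struct, ".")
    loops = [
        (s, ln)
        for s, ln in dot_runs
        if s > 0 and s + ln < length and struct[s - 1] == "(" and struct[s + ln] == ")"
    ]
    longest_unpaired = max((ln for _, ln in dot_runs), default=0)

    # stems: chains of consecutive nested pairs
    pair_set = set(pairs)
    stems: list[int] = []
    for i, j in pairs:
        if (i - 1, j + 1) in pair_set:
            continue  # not a stem start
        ln = 1
        while (i + ln, j - ln) in pair_set:
            ln += 1
        stems.append(ln)

    def pair_frac(kinds: set[frozenset]) -> float:
        if n_pairs == 0:
            return 0.0
        hits = sum(1 for i, j in pairs if frozenset((seq[i], seq[j])) in kinds)
        return hits / n_pairs

    out: dict[str, float] = {
        "pair_count": float(n_pairs),
        "pairs_per_length": n_pairs / length,
        "loop_count": float(len(loops)),
        "mean_loop_length": float(np.mean([ln for _, ln in loops])) if loops else 0.0,
        "longest_unpaired_run": float(longest_unpaired),
        "unpaired_fraction": struct.count(".") / length,
        "stem_count": float(len(stems)),
        "max_stem_length": float(max(stems, default=0)),
        "mean_stem_length": float(np.mean(stems)) if stems else 0.0,
        "gc_pair_fraction": pair_frac({frozenset(("G", "C"))}),
        "au_pair_fraction": pair_frac({frozenset(("A", "U"))}),
        "gu_pair_fraction": pair_frac({frozenset(("G", "U"))}),
    }

    if fold_result.energy is not None:
        mfe = fold_result.energy
        gc_pct = 100.0 * (seq.count("G") + seq.count("C")) / length
        out["mfe"] = mfe
        out["mfe_per_length"] = mfe / length
        out["mfei1"] = (mfe / length * 100.0) / gc_pct if gc_pct > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    group: str  # composition | triplet | structural | energy
    requires_structure: bool
    requires_energy: bool


@dataclass(frozen=True)
class FeatureCatalog:
    """The ordered feature list; catalog order defines table column order."""

    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate catalog feature names")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def version(self) -> str:
        digest = hashlib.sha1(",".join(self.names).encode()).hexdigest()[:8]
        return f"v1-{digest}"

    def without_energy(self) -> "FeatureCatalog":
        return FeatureCatalog(
            tuple(e for e in self.entries if not e.requires_energy)
        )


def default_catalog(include_energy: bool = True) -> FeatureCatalog:
    entries: list[CatalogEntry] = []

    def add(name, group, structure=False, energy=False):
        entries.append(CatalogEntry(name, group, structure, energy))

    add("length", "composition")
    add("gc_content", "composition")
    for b in BASES:
        add(f"freq_{b}", "composition")
    for dn in DINUCLEOTIDES:
        add(f"freq_{dn}", "composition")
    for b in BASES:
        for s in TRIPLET_STATUSES:
            add(f"triplet_{b}_{s}", "triplet", structure=True)
    for name in (
        "pair_count",
        "pairs_per_length",
        "loop_count",
        "mean_loop_length",
        "longest_unpaired_run",
        "unpaired_fraction",
        "stem_count",
        "max_stem_length",
        "mean_stem_length",
        "gc_pair_fraction",
        "au_pair_fraction",
        "gu_pair_fraction",
    ):
        add(name, "structural", structure=True)
    if include_energy:
        for name in ("mfe", "mfe_per_length", "mfei1"):
            add(name, "energy", structure=True, energy=True)
    return FeatureCatalog(tuple(entries))


# ---------------------------------------------------------------------------
# Record sets -> feature tables
# ---------------------------------------------------------------------------


def featurize_record(
    record: HairpinRecord, backend: str = "maxpair", catalog: FeatureCatalog | None = None
) -> dict[str, float]:
    if catalog is None:
        catalog = default_catalog(include_energy=backend in ENERGY_BACKENDS)
    fold_result = fold(record, backend=backend)
    feats: dict[str, float] = {}
    feats.update(composition_features(record))
    feats.update(triplet_features(record, fold_result))
    feats.update(structural_features(record, fold_result))
    return {e.name: feats[e.name] for e in catalog.entries}


def featurize_set(
    records: Iterable[HairpinRecord],
    backend: str = "maxpair",
    catalog: FeatureCatalog | None = None,
    labels: Iterable[str] | None = None,
) -> FeatureTable:
    """One row per record, columns in catalog order.

    Features requiring an energy are dropped from the default catalog
    when the backend cannot supply one.  Any per-record failure aborts
    with the offending record id.
    """
    records = list(records)
    if catalog is None:
        catalog = default_catalog(include_energy=backend in ENERGY_BACKENDS)
    elif backend not in ENERGY_BACKENDS:
        catalog = catalog.without_energy()
    rows = []
    for rec in records:
        try:
            feats = featurize_record(rec, backend=backend, catalog=catalog)
        except Exception as exc:
            raise RuntimeError(f"featurization failed for record {rec.id!r}: {exc}") from exc
        rows.append([feats[name] for name in catalog.names])
    if labels is None:
        label_arr = np.array([UNLABELED] * len(records), dtype=object)
    else:
        label_arr = np.array(list(labels), dtype=object)
    return FeatureTable(
        sample_ids=[rec.id for rec in records],
        feature_names=catalog.names,
        values=np.asarray(rows, dtype=float).reshape(len(records), len(catalog.names)),
        labels=label_arr,
    )
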