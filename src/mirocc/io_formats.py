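"""Reading and writing the workbench's on-disk formats.

Four artefact kinds flow through a pre-miRNA one-class-classification
experiment:

* hairpin sequences as FASTA, optionally with one dot-bracket secondary
  structure line immediately after each record's sequence block;
* feature tables (samples x named numeric features plus a class label);
* feature-selection results (ordered feature names with scores and
  provenance);
* evaluation reports (per-repeat metric rows plus an aggregate block).

Feature tables are CSV with a header row, the sample id in the first
column and the class label in a column named ``label`` (both
configurable).  Missing or non-numeric feature cells are fatal at load
time — every feature in the catalog is fully computable, so a hole in a
table always indicates an upstream bug, never censoring.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

TARGET = "target"
OUTLIER = "outlier"
UNLABELED = "unlabeled"
LABELS = (TARGET, OUTLIER, UNLABELED)

_STRUCTURE_CHARS = set(".()")


class FormatError(ValueError):
    """Raised when an on-disk artefact violates its format contract."""


# ---------------------------------------------------------------------------
# Hairpin records
# ---------------------------------------------------------------------------


def _check_structure(structure: str, seq_len: int, record_id: str) -> None:
    if len(structure) != seq_len:
        raise FormatError(
            f"record {record_id!r}: structure length {len(structure)} "
            f"!= sequence length {seq_len}"
        )
    bad = set(structure) - _STRUCTURE_CHARS
    if bad:
        raise FormatError(
            f"record {record_id!r}: invalid structure characters {sorted(bad)}"
        )
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"record {record_id!r}: unbalanced structure (early ')')"
                )
    if depth != 0:
        raise FormatError(
            f"record {record_id!r}: unbalanced structure ({depth} unclosed '(')"
        )


@dataclass(frozen=True)
class HairpinRecord:
    """One hairpin sequence, the unit of featurization.

    The sequence is normalized to uppercase RNA (T -> U).  When a
    dot-bracket ``structure`` is present it must be balanced and exactly
    as long as the sequence.
    """

    id: str
    sequence: str
    structure: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - set("ACGU")
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid sequence characters {sorted(bad)}"
            )
        if self.structure is not None:
            _check_structure(self.structure, len(seq), self.id)


def read_fasta(path, structure_lines: bool = False) -> list[HairpinRecord]:
    """Read hairpin records from FASTA.

    With ``structure_lines=True`` the last line of each record block must
    be a dot-bracket string covering the full sequence (the convention
    used by :func:`write_fasta`).  An empty file yields an empty list.
    """
    records: list[HairpinRecord] = []
    seen: set[str] = set()
    if not structure_lines:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(HairpinRecord(id=rec.id, sequence=str(rec.seq)))
        return records

    # Extended dialect: the line immediately after the sequence block is the
    # dot-bracket structure.  Parsed by hand — this is not standard FASTA.
    with open(path) as fh:
        blocks: list[tuple[str, list[str]]] = []
        header: str | None = None
        lines: list[str] = []
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    blocks.append((header, lines))
                header = line[1:].split()[0]
                lines = []
            else:
                if header is None:
                    raise FormatError("sequence data before first FASTA header")
                lines.append(line)
        if header is not None:
            blocks.append((header, lines))

    for rec_id, body in blocks:
        if rec_id in seen:
            raise FormatError(f"duplicate record id {rec_id!r}")
        seen.add(rec_id)
        if len(body) < 2:
            raise FormatError(
                f"record {rec_id!r}: expected a structure line after the sequence"
            )
        structure = body[-1]
        if set(structure) - _STRUCTURE_CHARS:
            raise FormatError(
                f"record {rec_id!r}: last line is not a dot-bracket structure"
            )
        sequence = "".join(body[:-1])
        records.append(
            HairpinRecord(id=rec_id, sequence=sequence, structure=structure)
        )
    return records


def write_fasta(records, path, structure_lines: bool = False) -> None:
    """Write hairpin records as FASTA, optionally with structure lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
            if structure_lines:
                if rec.structure is None:
                    raise FormatError(
                        f"record {rec.id!r} has no structure to write"
                    )
                fh.write(rec.structure + "\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Samples x named numeric features plus a per-sample class label.

    The currency of every stage of the workbench: featurization emits
    one, every selector and classifier consumes one.  All values must be
    finite; labels are ``target`` (true pre-miRNA), ``outlier`` (pseudo
    hairpin) or ``unlabeled``.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n, d = self.values.shape if self.values.ndim == 2 else (len(self.values), -1)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D matrix")
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise FormatError("sample ids / labels do not match matrix rows")
        if len(self.feature_names) != d:
            raise FormatError("feature names do not match matrix columns")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample ids")
        if len(set(self.feature_names)) != d:
            raise FormatError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_names[bad[1]]!r}"
            )
        bad_labels = set(self.labels) - set(LABELS)
        if bad_labels:
            raise FormatError(f"unknown labels {sorted(bad_labels)}")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def column(self, feature: str) -> np.ndarray:
        try:
            j = self.feature_names.index(feature)
        except ValueError:
            raise KeyError(f"feature {feature!r} not in table") from None
        return self.values[:, j]

    def subset_features(self, names) -> "FeatureTable":
        idx = []
        for name in names:
            try:
                idx.append(self.feature_names.index(name))
            except ValueError:
                raise KeyError(f"feature {name!r} not in table") from None
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            values=self.values[:, idx],
            labels=self.labels.copy(),
        )

    def subset_samples(self, row_idx) -> "FeatureTable":
        row_idx = np.asarray(row_idx)
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in row_idx],
            feature_names=list(self.feature_names),
            values=self.values[row_idx],
            labels=self.labels[row_idx],
        )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )
        df.index.name = "sample_id"
        df[label_column] = self.labels
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str = "label"
    ) -> "FeatureTable":
        if label_column not in df.columns:
            raise FormatError(f"label column {label_column!r} missing")
        labels = df[label_column].astype(str).to_numpy(dtype=object)
        feats = df.drop(columns=[label_column])
        for col in feats.columns:
            coerced = pd.to_numeric(feats[col], errors="coerce")
            bad = coerced.isna() & feats[col].notna()
            if bad.any():
                row = feats.index[bad.argmax()]
                raise FormatError(
                    f"non-numeric value in column {col!r}, row {row!r}"
                )
            if coerced.isna().any():
                row = feats.index[coerced.isna().argmax()]
                raise FormatError(f"missing value in column {col!r}, row {row!r}")
            feats[col] = coerced
        return cls(
            sample_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in feats.columns],
            values=feats.to_numpy(dtype=float),
            labels=labels,
        )


def read_feature_table(
    path, label_column: str = "label", delimiter: str = ","
) -> FeatureTable:
    """Load a delimited feature table; column order is preserved."""
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=object)
    return FeatureTable.from_dataframe(df, label_column=label_column)


def write_feature_table(
    table: FeatureTable, path, label_column: str = "label", delimiter: str = ","
) -> None:
    table.to_dataframe(label_column=label_column).to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# Selection results
# ---------------------------------------------------------------------------

_SELECTION_MAGIC = "# mirocc selection v1"


def write_selection(result, path) -> None:
    """Persist a SelectionResult: provenance header plus ordered rows."""
    with open(path, "w") as fh:
        fh.write(_SELECTION_MAGIC + "\n")
        fh.write(f"# method: {result.method}\n")
        fh.write(f"# seed: {result.seed}\n")
        fh.write(f"# n_requested: {result.n_requested}\n")
        fh.write(f"# params: {json.dumps(result.params, sort_keys=True)}\n")
        fh.write(f"# shortfall: {json.dumps(result.shortfall)}\n")
        fh.write("rank,feature,score\n")
        for rank, name in enumerate(result.selected, start=1):
            score = result.scores.get(name) if result.scores else None
            score_txt = "" if score is None else repr(float(score))
            fh.write(f"{rank},{name},{score_txt}\n")


def read_selection(path):
    """Inverse of :func:`write_selection`."""
    from .select import SelectionResult  # local import to avoid a cycle

    meta: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _SELECTION_MAGIC:
            raise FormatError(f"{path}: not a mirocc selection file")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition(": ")
                meta[key] = val
            elif line and line != "rank,feature,score":
                _, name, score = line.split(",")
                rows.append((name, score))
    selected = [name for name, _ in rows]
    scores = {
        name: float(score) for name, score in rows if score != ""
    } or None
    return SelectionResult(
        method=meta["method"],
        selected=selected,
        scores=scores,
        seed=int(meta["seed"]),
        params=json.loads(meta.get("params", "{}")),
        n_requested=int(meta["n_requested"]),
        shortfall=json.loads(meta.get("shortfall", "false")),
    )


# ---------------------------------------------------------------------------
# Evaluation reports
# ---------------------------------------------------------------------------

_REPORT_MAGIC = "# mirocc report v1"
METRICS = ("sensitivity", "specificity", "balanced_accuracy", "pooled_accuracy")


def write_report(report, path) -> None:
    """Persist an EvalReport: per-repeat rows plus an aggregate block."""
    with open(path, "w") as fh:
        fh.write(_REPORT_MAGIC + "\n")
        fh.write(f"# dataset: {report.dataset}\n")
        fh.write(f"# method: {report.method}\n")
        fh.write(f"# seed: {report.seed}\n")
        fh.write(f"# n_repeats: {report.n_repeats}\n")
        fh.write("block,repeat," + ",".join(METRICS) + "\n")
        for i, row in report.rows.iterrows():
            vals = ",".join(repr(float(row[m])) for m in METRICS)
            fh.write(f"repeat,{i},{vals}\n")
        agg = report.aggregate()
        for stat in ("mean", "std"):
            vals = ",".join(repr(float(agg.loc[stat, m])) for m in METRICS)
            fh.write(f"aggregate,{stat},{vals}\n")


def read_report(path):
    from .evaluate import EvalReport  # local import to avoid a cycle

    meta: dict[str, str] = {}
    repeat_lines: list[str] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _REPORT_MAGIC:
            raise FormatError(f"{path}: not a mirocc report file")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition(": ")
                meta[key] = val
            elif line.startswith("repeat,"):
                repeat_lines.append(line)
    buf = io.StringIO(
        "block,repeat," + ",".join(METRICS) + "\n" + "\n".join(repeat_lines)
    )
    df = pd.read_csv(buf).set_index("repeat")[list(METRICS)]
    df.index = df.index.astype(int)
    return EvalReport(
        dataset=meta["dataset"],
        method=meta["method"],
        seed=int(meta["seed"]),
        rows=df,
    )
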