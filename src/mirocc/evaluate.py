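"""The repeated-holdout evaluation protocol and method comparison.

Each repeat samples 90% of the target (positive) rows for training and
holds out the remaining 10%; the *entire* outlier pool joins the test
side every repeat — outliers are never trained on, which is the point of
one-class classification.  Metrics per repeat:

* sensitivity  = accepted test targets / test targets
* specificity  = rejected outliers / outliers
* balanced accuracy = (sensitivity + specificity) / 2
* pooled accuracy   = correct decisions / all test samples

The headline figure is balanced accuracy: with ~10 test targets against
a ~1000-strong outlier pool, pooled accuracy is dominated by specificity
and nearly blind to the target class.  Both are reported.

Feature selection runs once on the full labeled table before the repeat
loop (the classic workflow: select per dataset, then repeat holdout).
That leaks selection information into the test folds; pass
``strict=True`` to re-select inside every repeat on the training targets
plus the outlier pool with the test targets withheld.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import FeatureTable, METRICS, OUTLIER, TARGET
from .occ import fit_occ, predict_occ
from .select import SelectionResult, select_features


@dataclass
class EvalReport:
    """Per-repeat metric rows plus their aggregate for one (dataset, method)."""

    dataset: str
    method: str
    seed: int
    rows: pd.DataFrame  # index: repeat, columns: METRICS
    selection: SelectionResult | None = None

    @property
    def n_repeats(self) -> int:
        return len(self.rows)

    def aggregate(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.rows.mean(), "std": self.rows.std(ddof=1).fillna(0.0)}
        ).T[list(METRICS)]


def holdout_split(
    table: FeatureTable,
    fraction_train: float = 0.9,
    repeat_index: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row indices for (train targets, test targets, test outliers).

    Targets are shuffled by a stream derived from (seed, repeat_index);
    the first ceil(fraction_train * n) go to training.  All outlier rows
    are test rows.
    """
    if not 0.0 < fraction_train < 1.0:
        raise ValueError("fraction_train must be in (0, 1)")
    target_rows = np.flatnonzero(table.label_mask(TARGET))
    outlier_rows = np.flatnonzero(table.label_mask(OUTLIER))
    if target_rows.size < 10:
        raise ValueError(f"need >= 10 target rows, got {target_rows.size}")
    rng = np.random.default_rng([seed, repeat_index])
    shuffled = rng.permutation(target_rows)
    n_train = math.ceil(fraction_train * target_rows.size)
    return shuffled[:n_train], shuffled[n_train:], outlier_rows


def _metrics_row(
    pred_target_labels: np.ndarray, pred_outlier_labels: np.ndarray
) -> dict[str, float]:
    n_t = pred_target_labels.size
    n_o = pred_outlier_labels.size
    tp = int(np.sum(pred_target_labels == TARGET))
    tn = int(np.sum(pred_outlier_labels == OUTLIER))
    sens = tp / n_t if n_t else 0.0
    spec = tn / n_o if n_o else 0.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
        "pooled_accuracy": (tp + tn) / (n_t + n_o) if (n_t + n_o) else 0.0,
    }


def run_experiment(
    table: FeatureTable,
    method: str,
    n_features: int = 50,
    occ_kind: str = "gauss_dd",
    n_repeats: int = 100,
    seed: int = 0,
    fraction_train: float = 0.9,
    rejection_fraction: float = 0.05,
    regularization: float = 1e-3,
    k_neighbors: int = 5,
    strict: bool = False,
    dataset: str = "dataset",
    selection_params: dict | None = None,
    selection: SelectionResult | None = None,
) -> EvalReport:
    """Select features, then run the repeated 90/10 one-class protocol.

    A precomputed ``selection`` (e.g. a combined cross-dataset set)
    bypasses the selection step.  With ``strict=True`` selection is
    re-run inside each repeat without the held-out test targets.
    """
    selection_params = dict(selection_params or {})
    if selection is None and not strict:
        selection = select_features(
            table, method, n=n_features, seed=seed, **selection_params
        )
    rows = []
    for r in range(n_repeats):
        train_t, test_t, test_o = holdout_split(
            table, fraction_train=fraction_train, repeat_index=r, seed=seed
        )
        if strict:
            visible = np.concatenate([train_t, test_o])
            sel_r = select_features(
                table.subset_samples(np.sort(visible)),
                method,
                n=n_features,
                seed=seed,
                **selection_params,
            )
        else:
            sel_r = selection
        sub = table.subset_features(list(sel_r.selected))
        model = fit_occ(
            sub.subset_samples(train_t),
            kind=occ_kind,
            rejection_fraction=rejection_fraction,
            regularization=regularization,
            k_neighbors=k_neighbors,
            seed=seed,
        )
        pred_t, _ = predict_occ(model, sub.subset_samples(test_t))
        pred_o, _ = predict_occ(model, sub.subset_samples(test_o))
        rows.append(_metrics_row(pred_t, pred_o))
    df = pd.DataFrame(rows)
    df.index.name = "repeat"
    return EvalReport(
        dataset=dataset,
        method=method.upper(),
        seed=seed,
        rows=df[list(METRICS)],
        selection=selection,
    )


@dataclass
class ComparisonResult:
    """Cross-method comparison for one dataset."""

    table: pd.DataFrame  # one row per method, sorted by mean balanced accuracy
    accuracy_gap: float  # max - min mean balanced accuracy across methods


def compare_methods(reports: list[EvalReport]) -> ComparisonResult:
    """Tabulate aggregate metrics and accuracy quartiles per method.

    All reports must share a dataset id.  Output rows are ordered by
    descending mean balanced accuracy; the gap is max - min of that
    column, recomputed from the per-repeat rows.
    """
    datasets = {r.dataset for r in reports}
    if len(datasets) > 1:
        raise ValueError(f"reports span multiple datasets: {sorted(datasets)}")
    recs = []
    for rep in reports:
        agg = rep.aggregate()
        acc = rep.rows["balanced_accuracy"]
        recs.append(
            {
                "method": rep.method,
                **{f"mean_{m}": agg.loc["mean", m] for m in METRICS},
                **{f"std_{m}": agg.loc["std", m] for m in METRICS},
                "acc_q1": float(acc.quantile(0.25)),
                "acc_median": float(acc.quantile(0.5)),
                "acc_q3": float(acc.quantile(0.75)),
            }
        )
    df = pd.DataFrame(recs).sort_values(
        ["mean_balanced_accuracy", "method"], ascending=[False, True]
    ).reset_index(drop=True)
    gap = float(
        df["mean_balanced_accuracy"].max() - df["mean_balanced_accuracy"].min()
    )
    return ComparisonResult(table=df, accuracy_gap=gap)
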