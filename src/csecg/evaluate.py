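"""Evaluation: confusion matrices, AAMI metric suite, and both protocols.

Per class, one-vs-rest counts (TP, TN, FP, FN) yield four rates:

    sensitivity            = TP / (TP + FN)
    specificity            = TN / (TN + FP)
    positive productivity  = TP / (TP + FP)      (one-vs-rest precision)
    accuracy               = (TP + TN) / (TP + TN + FP + FN)

all reported as percentages. The **macro** row is the unweighted mean of
the five per-class values; the **aggregate** row is the gross (micro)
statistic computed from the classwise-summed counts. Protocols:

* **intra-patient** — stratified beat-wise 10-fold cross-validation; the
  per-fold confusion matrices are summed into one pooled matrix and metrics
  are taken from the pool (so classes too rare to appear in every fold are
  still scored);
* **inter-patient** — one model trained on the DS1 records' segments,
  evaluated once on DS2, with disjointness of the record sets asserted
  before training.

``MITBIH_INTRA_CONFUSION`` and ``MITBIH_INTER_TEST_CONFUSION`` are the
published pooled confusion matrices obtained with this method on the full
MIT-BIH arrhythmia database (intra-patient 10-fold, and the DS2 test set of
the inter-patient split). They are reference inputs for the metric suite:
recomputing the metric tables from them reproduces the published per-class
and macro percentages, which is how this package validates its metric
definitions without the external database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ecg_io import AAMI_CLASSES
from .model import BeatClassifier, ModelConfig, TrainConfig
from .segment import SegmentDataset

logger = logging.getLogger(__name__)

#: Published intra-patient pooled confusion matrix (rows true, cols
#: predicted, class order N, S, V, F, Q) on the 44-record database.
MITBIH_INTRA_CONFUSION = np.array([
    [89820, 117, 34, 4, 1],
    [122, 2636, 16, 0, 0],
    [59, 13, 6895, 35, 0],
    [32, 3, 39, 728, 0],
    [1, 0, 4, 1, 9],
])

#: Published inter-patient confusion matrix on the DS2 test records.
MITBIH_INTER_TEST_CONFUSION = np.array([
    [40629, 1832, 645, 989, 90],
    [321, 1427, 83, 1, 3],
    [224, 156, 2788, 29, 20],
    [53, 4, 50, 264, 17],
    [2, 0, 3, 0, 2],
])


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_order: tuple[str, ...] = AAMI_CLASSES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        C = len(self.class_order)
        if counts.shape != (C, C) or np.any(counts < 0):
            raise ValueError(f"counts must be a nonnegative {C}x{C} matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_order != other.class_order:
            raise ValueError("cannot pool matrices with different class orders")
        return ConfusionMatrix(self.counts + other.counts, self.class_order)

    def one_vs_rest(self) -> np.ndarray:
        """Per-class (TP, TN, FP, FN) counts, shape (C, 4)."""
        cm = self.counts
        total = cm.sum()
        tp = np.diag(cm).astype(np.int64)
        fn = cm.sum(axis=1) - tp
        fp = cm.sum(axis=0) - tp
        tn = total - tp - fn - fp
        return np.stack([tp, tn, fp, fn], axis=1)


_METRIC_NAMES = ("accuracy", "sensitivity", "specificity",
                 "positive_productivity")


@dataclass(frozen=True)
class MetricsReport:
    """Per-class, macro and aggregate rates (percent, full precision)."""

    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    aggregate: dict[str, float]
    confusion: ConfusionMatrix | None = field(default=None, compare=False)

    def rounded(self, decimals: int = 2) -> "MetricsReport":
        """Display copy with half-up rounding (as the tables print)."""
        def r(v: float) -> float:
            return float("nan") if np.isnan(v) else _round_half_up(v, decimals)

        return MetricsReport(
            per_class={c: {k: r(v) for k, v in row.items()}
                       for c, row in self.per_class.items()},
            macro={k: r(v) for k, v in self.macro.items()},
            aggregate={k: r(v) for k, v in self.aggregate.items()},
            confusion=self.confusion,
        )

    def to_text(self) -> str:
        lines = [f"{'class':<10}" + "".join(f"{m:>22}" for m in _METRIC_NAMES)]
        rows = list(self.per_class.items()) + [
            ("Macro", self.macro), ("Aggregate", self.aggregate)]
        for name, row in rows:
            lines.append(
                f"{name:<10}" + "".join(
                    f"{row[m]:>21.2f}%" if not np.isnan(row[m]) else
                    f"{'n/a':>22}" for m in _METRIC_NAMES)
            )
        return "\n".join(lines)


def _round_half_up(value: float, decimals: int) -> float:
    factor = 10.0 ** decimals
    return float(np.floor(value * factor + 0.5) / factor)


def confusion(
    true_labels: np.ndarray, predicted_labels: np.ndarray,
    C: int = len(AAMI_CLASSES),
) -> ConfusionMatrix:
    """Count matrix: entry (i, j) = samples with true class i predicted j."""
    true_labels = np.asarray(true_labels, dtype=int)
    predicted_labels = np.asarray(predicted_labels, dtype=int)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label sequences must have the same length")
    counts = np.zeros((C, C), dtype=np.int64)
    np.add.at(counts, (true_labels, predicted_labels), 1)
    return ConfusionMatrix(counts, AAMI_CLASSES[:C])


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest rates per class, plus macro and aggregate rollups.

    A class with zero true and zero predicted samples has undefined
    sensitivity/positive productivity; those entries are NaN and excluded
    from the macro mean.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    ovr = cm.one_vs_rest()
    per_class: dict[str, dict[str, float]] = {}
    for name, (tp, tn, fp, fn) in zip(cm.class_order, ovr):
        per_class[name] = {
            "accuracy": 100.0 * (tp + tn) / (tp + tn + fp + fn),
            "sensitivity": _rate(tp, tp + fn),
            "specificity": _rate(tn, tn + fp),
            "positive_productivity": _rate(tp, tp + fp),
        }
    report = MetricsReport(
        per_class=per_class,
        macro=macro_metrics(per_class),
        aggregate=aggregate_metrics(cm),
        confusion=cm,
    )
    return report


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def macro_metrics(per_class: dict[str, dict[str, float]]) -> dict[str, float]:
    """Unweighted mean of the per-class rates (NaN entries excluded)."""
    macro: dict[str, float] = {}
    for metric in _METRIC_NAMES:
        values = [row[metric] for row in per_class.values()
                  if not np.isnan(row[metric])]
        macro[metric] = float(np.mean(values)) if values else float("nan")
    return macro


def aggregate_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Gross (micro) rates from the classwise-summed one-vs-rest counts."""
    tp, tn, fp, fn = cm.one_vs_rest().sum(axis=0)
    return {
        "accuracy": 100.0 * (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": _rate(tp, tp + fn),
        "specificity": _rate(tn, tn + fp),
        "positive_productivity": _rate(tp, tp + fp),
    }


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def stratified_folds(
    y: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Beat-wise stratified k-fold assignment (per-class round robin).

    Classes with fewer than k members are spread best-effort over the first
    folds. Per class, fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        if idx.size < k:
            logger.info(
                "class %s has %d < k=%d samples; folded best-effort",
                AAMI_CLASSES[c] if c < len(AAMI_CLASSES) else c, idx.size, k,
            )
        for fold, chunk in enumerate(np.array_split(idx, k)):
            folds[fold].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def run_intra_patient(
    dataset: SegmentDataset,
    k: int = 10,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation with a pooled confusion matrix.

    Each fold trains a fresh model on the other k-1 folds and is scored on
    the held-out fold; the per-fold matrices are summed and metrics taken
    from the pool. Deterministic given ``seed``.
    """
    folds = stratified_folds(dataset.y, k, seed)
    pooled = ConfusionMatrix(np.zeros((len(AAMI_CLASSES),) * 2, dtype=int))
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(dataset)), test_idx)
        base = model_config or ModelConfig.small()
        config = ModelConfig(**{**_asdict(base), "seed": seed + 1000 * fold_id})
        clf = BeatClassifier(config)
        clf.fit(dataset.subset(train_idx), train_config)
        preds = clf.predict(dataset.X[test_idx])
        pooled = pooled + confusion(dataset.y[test_idx], preds)
    assert pooled.total == len(dataset)
    return per_class_metrics(pooled)


def run_inter_patient(
    train: SegmentDataset,
    test: SegmentDataset,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> dict[str, MetricsReport]:
    """Train once on the DS1-style split, evaluate on both splits.

    Returns ``{"train": ..., "test": ...}`` reports. Overlapping record
    sets are a protocol error.
    """
    train_records = {r for r in train.record_ids if r}
    test_records = {r for r in test.record_ids if r}
    overlap = train_records & test_records
    if overlap:
        raise ValueError(
            f"records in both training and test splits: {sorted(overlap)}"
        )
    clf = BeatClassifier(model_config or ModelConfig.small())
    clf.fit(train, train_config)
    out: dict[str, MetricsReport] = {}
    for name, ds in (("train", train), ("test", test)):
        preds = clf.predict(ds.X)
        out[name] = per_class_metrics(confusion(ds.y, preds))
    return out


def compare_losses(
    train: SegmentDataset,
    test: SegmentDataset,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    model_config: ModelConfig | None = None,
    epochs: int = 10,
    batch_size: int = 128,
    lr: float = 0.01,
) -> dict:
    """Paired cost-sensitive vs cross-entropy arms on identical data.

    For each seed both arms share the model architecture, initial weights,
    schedule and batch order, differing only in the loss. Returns per-arm
    mean metric reports plus per-metric differences (cost-sensitive minus
    cross-entropy), including the minority-class (S, V, F) macro
    sensitivity the imbalance treatment targets.
    """
    base = model_config or ModelConfig.small()
    results: dict[str, list[MetricsReport]] = {"cs": [], "ce": []}
    minority = [AAMI_CLASSES.index(c) for c in ("S", "V", "F")]
    minority_sens: dict[str, list[float]] = {"cs": [], "ce": []}
    for seed in seeds:
        for loss in ("cs", "ce"):
            config = ModelConfig(**{**_asdict(base), "seed": int(seed)})
            clf = BeatClassifier(config)
            tc = TrainConfig(epochs=epochs, batch_size=batch_size, lr=lr,
                             loss=loss)
            clf.fit(train, tc)
            report = per_class_metrics(confusion(test.y, clf.predict(test.X)))
            results[loss].append(report)
            sens = [report.per_class[AAMI_CLASSES[c]]["sensitivity"]
                    for c in minority]
            sens = [s for s in sens if not np.isnan(s)]
            minority_sens[loss].append(float(np.mean(sens)))
    summary = {
        arm: {
            "macro_sensitivity": float(np.mean(
                [r.macro["sensitivity"] for r in results[arm]])),
            "macro_positive_productivity": float(np.nanmean(
                [r.macro["positive_productivity"] for r in results[arm]])),
            "minority_sensitivity": float(np.mean(minority_sens[arm])),
            "reports": results[arm],
        }
        for arm in ("cs", "ce")
    }
    summary["delta"] = {
        "minority_sensitivity":
            summary["cs"]["minority_sensitivity"]
            - summary["ce"]["minority_sensitivity"],
        "macro_sensitivity":
            summary["cs"]["macro_sensitivity"]
            - summary["ce"]["macro_sensitivity"],
    }
    summary["seeds"] = list(seeds)
    return summary


def _asdict(config: ModelConfig) -> dict:
    from dataclasses import asdict
    return asdict(config)
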