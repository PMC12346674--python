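"""Metrics, the two training protocols, and rapid-detection analysis.

Metrics are the standard one-vs-rest confusion quantities per class —

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

— macro-averaged (unweighted mean over classes) and reported in percent.
Overall accuracy is reported as the conventional multiclass fraction
correct; the one-vs-rest mean variant is available via ``accuracy_mode``.

Two experiment protocols slice each measurement into per-second instances:
group 1 uses the full 1..120 s window, group 2 uses 21..120 s only, because
the sample gas may not fully reach the array within the first 20 s.  The
train/test split is stratified at the *record* level before slicing, so no
measurement contributes instances to both sides.  Test records are also
scored second by second; the first second at which that accuracy curve
attains its maximum is the recommended gas-collection time for rapid
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .data_model import Dataset, InstanceTable, slice_instances
from .model import (
    ModelConfig,
    ParameterSet,
    Standardizer,
    TrainingConfig,
    TrainingHistory,
    forward_batch,
    train,
)


@dataclass
class ConfusionTally:
    """One-vs-rest TP/FP/TN/FN counts per class."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


def tally(preds: np.ndarray, truth: np.ndarray, n_classes: int) -> ConfusionTally:
    """Build per-class one-vs-rest tallies from predicted and true labels."""
    preds = np.asarray(preds, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if preds.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {preds.shape} predictions vs {truth.shape} labels"
        )
    for arr, what in ((preds, "prediction"), (truth, "label")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{what} outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (truth, preds), 1)
    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    return ConfusionTally(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class MetricsReport:
    """Macro-averaged scores in percent, plus any zero-denominator classes."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    degenerate_classes: list[int] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
        }


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def metrics(t: ConfusionTally, accuracy_mode: str = "overall") -> MetricsReport:
    """Macro-average the per-class scores; zero-denominator classes score 0.

    ``accuracy_mode='overall'`` reports the multiclass fraction correct;
    ``'ovr'`` reports the mean of the per-class one-vs-rest accuracies.
    """
    if t.total == 0:
        raise ValueError("empty tally")
    tp, fp, tn, fn = (
        t.tp.astype(float), t.fp.astype(float), t.tn.astype(float),
        t.fn.astype(float),
    )
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2.0 * precision * recall, precision + recall)
    if accuracy_mode == "overall":
        accuracy = float(tp.sum() / t.total)
    elif accuracy_mode == "ovr":
        accuracy = float(np.mean((tp + tn) / (tp + tn + fp + fn)))
    else:
        raise ValueError(f"unknown accuracy_mode {accuracy_mode!r}")
    degenerate = sorted(
        set(np.flatnonzero(tp + fp == 0)) | set(np.flatnonzero(tp + fn == 0))
    )
    return MetricsReport(
        accuracy=100.0 * accuracy,
        precision=100.0 * float(precision.mean()),
        recall=100.0 * float(recall.mean()),
        specificity=100.0 * float(specificity.mean()),
        f1=100.0 * float(f1.mean()),
        degenerate_classes=[int(i) for i in degenerate],
    )


@dataclass
class AccuracyCurve:
    """Per-second test accuracy over the protocol window (fractions in [0,1])."""

    seconds: np.ndarray    # 1-based second indices, window order
    accuracy: np.ndarray   # same length, values in [0, 1]

    def __len__(self) -> int:
        return len(self.seconds)

    def mean(self) -> float:
        return float(self.accuracy.mean())

    def over(self, t_start: int, t_end: int) -> np.ndarray:
        """Accuracy values for seconds in [t_start, t_end] (inclusive)."""
        mask = (self.seconds >= t_start) & (self.seconds <= t_end)
        return self.accuracy[mask]


def earliest_peak(curve: AccuracyCurve) -> tuple[int, float]:
    """First second at which the curve attains its maximum.

    This is the recommended gas-collection duration: past it, waiting
    longer buys no accuracy.
    """
    if len(curve) == 0:
        raise ValueError("empty accuracy curve")
    i = int(np.argmax(curve.accuracy))   # argmax takes the first maximum
    return int(curve.seconds[i]), float(curve.accuracy[i])


PROTOCOL_WINDOWS = {1: (1, None), 2: (21, None)}


def protocol_window(group: int, duration: int) -> tuple[int, int]:
    if group not in PROTOCOL_WINDOWS:
        raise ValueError("protocol group must be 1 or 2")
    start, _ = PROTOCOL_WINDOWS[group]
    return (start, duration)


@dataclass
class ProtocolResult:
    report: MetricsReport
    curve: AccuracyCurve
    params: ParameterSet
    standardizer: Standardizer
    history: TrainingHistory
    train_records: list[str]
    test_records: list[str]
    train_instances: InstanceTable
    test_instances: InstanceTable


def split_records(
    dataset: Dataset, test_fraction: float, seed: int
) -> tuple[list[int], list[int]]:
    """Class-stratified record-level split; returns record indices."""
    labels = dataset.class_labels()
    counts = np.bincount(labels)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 records to stratify")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    return sorted(train_idx.tolist()), sorted(test_idx.tolist())


def run_protocol(
    dataset: Dataset,
    group: int,
    config: ModelConfig,
    tc: TrainingConfig,
    seed: int | None = None,
) -> ProtocolResult:
    """Train and evaluate under one experiment protocol.

    Splits records 7:3 stratified by class, slices the protocol window into
    per-second instances, standardizes with training-split statistics (if
    enabled), trains, and reports both overall test metrics and the
    second-by-second accuracy curve.  Fully reproducible given the seed.
    """
    seed = tc.seed if seed is None else seed
    tc = TrainingConfig(**{**tc.__dict__, "seed": seed})
    window = protocol_window(group, dataset.design.n_seconds)

    train_idx, test_idx = split_records(dataset, 1.0 - tc.train_fraction, seed)
    train_ds = Dataset([dataset.records[i] for i in train_idx], dataset.design)
    test_ds = Dataset([dataset.records[i] for i in test_idx], dataset.design)
    train_tab = slice_instances(train_ds, window)
    test_tab = slice_instances(test_ds, window)

    if tc.standardize:
        std = Standardizer.fit(train_tab.X)
    else:
        std = Standardizer.identity(train_tab.X.shape[1])
    params, history = train(config, train_tab, tc, X=std.transform(train_tab.X))

    test_X = std.transform(test_tab.X)
    preds = np.argmax(forward_batch(config, params, test_X), axis=1)
    report = metrics(tally(preds, test_tab.y, config.n_classes))

    seconds = np.arange(window[0], window[1] + 1)
    correct = preds == test_tab.y
    acc = np.array([correct[test_tab.t == s].mean() for s in seconds])
    curve = AccuracyCurve(seconds=seconds, accuracy=acc)

    return ProtocolResult(
        report=report,
        curve=curve,
        params=params,
        standardizer=std,
        history=history,
        train_records=[dataset.records[i].record_id for i in train_idx],
        test_records=[dataset.records[i].record_id for i in test_idx],
        train_instances=train_tab,
        test_instances=test_tab,
    )


def repeated_runs(
    dataset: Dataset,
    group: int,
    config: ModelConfig,
    tc: TrainingConfig,
    seeds: list[int],
) -> tuple[MetricsReport, list[ProtocolResult]]:
    """Repeat a protocol over several seeds and mean-aggregate the metrics."""
    if not seeds:
        raise ValueError("need at least one seed")
    results = [run_protocol(dataset, group, config, tc, seed=s) for s in seeds]
    mean = {
        k: float(np.mean([r.report.as_dict()[k] for r in results]))
        for k in results[0].report.as_dict()
    }
    return MetricsReport(**mean), results
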