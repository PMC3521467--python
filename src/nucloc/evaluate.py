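"""Confusion counts, the four evaluation measures, and cross-validation.

The nuclear class is the positive class.  Metrics:

* sensitivity = tp / (tp + fn)
* specificity = tn / (tn + fp)
* accuracy    = (tp + tn) / N
* MCC         = (tp*tn - fp*fn) / sqrt((tp+fn)(tp+fp)(tn+fp)(tn+fn))

Any metric whose denominator is zero is reported as ``None`` (undefined),
never silently as 0.  Cross-validation pools confusion counts over folds
(micro-averaging) before computing metrics.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import pipeline as pipeline_mod
from .signatures import CLASSES, NUCLEAR


class LeakageError(RuntimeError):
    """Raised when a fitting stage reads a held-out label."""


class _TrackedLabels(Mapping):
    """Mapping wrapper that records which protein labels were read."""

    def __init__(self, labels: Mapping[str, str]):
        self._labels = dict(labels)
        self.accessed: set[str] = set()

    def __getitem__(self, key: str) -> str:
        self.accessed.add(key)
        return self._labels[key]

    def __iter__(self):
        return iter(self._labels)

    def __len__(self) -> int:
        return len(self._labels)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def N(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricReport:
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    mcc: float | None

    def rounded(self, digits: int = 3) -> dict[str, float | None]:
        return {
            name: (None if value is None else round(value, digits))
            for name, value in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("accuracy", self.accuracy),
                ("mcc", self.mcc),
            )
        }


def confusion_from_predictions(
    truth: Mapping[str, str], predicted: Mapping[str, str]
) -> ConfusionCounts:
    """Tally a confusion table; the id sets must coincide."""
    if set(truth) != set(predicted):
        only_truth = sorted(set(truth) - set(predicted))
        only_pred = sorted(set(predicted) - set(truth))
        raise ValueError(
            f"id mismatch between truth and predictions: only in truth {only_truth}, "
            f"only in predictions {only_pred}"
        )
    tp = tn = fp = fn = 0
    for pid, actual in truth.items():
        pred = predicted[pid]
        if actual not in CLASSES or pred not in CLASSES:
            raise ValueError(f"unknown class for {pid!r}: {actual!r}/{pred!r}")
        if actual == NUCLEAR:
            if pred == NUCLEAR:
                tp += 1
            else:
                fn += 1
        else:
            if pred == NUCLEAR:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def compute_metrics(cc: ConfusionCounts) -> MetricReport:
    if cc.N < 1:
        raise ValueError("cannot compute metrics on empty counts")
    tp, tn, fp, fn = cc.tp, cc.tn, cc.fp, cc.fn
    sens = tp / (tp + fn) if tp + fn > 0 else None
    spec = tn / (tn + fp) if tn + fp > 0 else None
    acc = (tp + tn) / cc.N
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return MetricReport(sens, spec, acc, mcc)


@dataclass(frozen=True)
class FoldOutcome:
    fold: int
    test_ids: tuple[str, ...]
    counts: ConfusionCounts
    report: MetricReport


@dataclass(frozen=True)
class CVResult:
    folds: tuple[FoldOutcome, ...]
    pooled_counts: ConfusionCounts
    pooled_report: MetricReport


def stratified_folds(
    labels: Mapping[str, str], folds: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """Seeded stratified partition into (train_ids, test_ids) pairs."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {cls: [] for cls in CLASSES}
    for pid in sorted(labels):
        by_class[labels[pid]].append(pid)
    minority = min(len(v) for v in by_class.values())
    if folds > minority:
        raise ValueError(f"folds={folds} exceeds minority class size {minority}")
    assignments: dict[str, int] = {}
    for cls, ids in by_class.items():
        ids = list(ids)
        rng.shuffle(ids)
        for i, pid in enumerate(ids):
            assignments[pid] = i % folds
    out = []
    for k in range(folds):
        test = [pid for pid in sorted(labels) if assignments[pid] == k]
        train = [pid for pid in sorted(labels) if assignments[pid] != k]
        out.append((train, test))
    return out


def cross_validate(
    dataset: "pipeline_mod.LabeledDataset",
    config: "pipeline_mod.PipelineConfig",
    folds: int | None = None,
    seed: int | None = None,
) -> CVResult:
    """Per fold: fit the whole pipeline on the training split only (PLSI,
    signatures and SVM all see only training labels — enforced by a label
    access tracker), fold in and predict the held-out proteins, then pool
    confusion counts over folds."""
    folds = config.folds if folds is None else folds
    seed = config.seed if seed is None else seed
    splits = stratified_folds(dataset.labels, folds, seed)
    outcomes: list[FoldOutcome] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for k, (train_ids, test_ids) in enumerate(splits):
        train = dataset.subset(train_ids)
        tracked = _TrackedLabels(train.labels)
        fitted = pipeline_mod.fit_pipeline(
            pipeline_mod.LabeledDataset(train.records, train.profiles, tracked),
            replace_seed(config, seed + k),
        )
        leaked = tracked.accessed - set(train_ids)
        if leaked:
            raise LeakageError(f"fold {k}: fitting read held-out labels {sorted(leaked)}")
        test = dataset.subset(test_ids)
        preds = pipeline_mod.predict_pipeline(fitted, test.records, test.profiles)
        predicted = {pid: info["class"] for pid, info in preds.items()}
        counts = confusion_from_predictions(dict(test.labels), predicted)
        outcomes.append(FoldOutcome(k, tuple(test_ids), counts, compute_metrics(counts)))
        pooled = pooled + counts
    return CVResult(tuple(outcomes), pooled, compute_metrics(pooled))


def replace_seed(config: "pipeline_mod.PipelineConfig", seed: int):
    return replace(config, seed=seed)


def write_report(result: CVResult, tsv_path: str | os.PathLike, json_path: str | os.PathLike | None = None) -> None:
    """TSV (one row per fold plus pooled) and an optional JSON twin."""
    rows = [(f"fold{o.fold}", o.counts, o.report) for o in result.folds]
    rows.append(("pooled", result.pooled_counts, result.pooled_report))
    with open(tsv_path, "w") as fh:
        fh.write("split\ttp\ttn\tfp\tfn\tsensitivity\tspecificity\taccuracy\tmcc\n")
        for name, cc, rep in rows:
            r = rep.rounded()
            fh.write(
                f"{name}\t{cc.tp}\t{cc.tn}\t{cc.fp}\t{cc.fn}\t"
                f"{r['sensitivity']}\t{r['specificity']}\t{r['accuracy']}\t{r['mcc']}\n"
            )
    if json_path is not None:
        payload = {
            name: {"tp": cc.tp, "tn": cc.tn, "fp": cc.fp, "fn": cc.fn, **rep.rounded()}
            for name, cc, rep in rows
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
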