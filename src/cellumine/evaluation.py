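"""Confusion-matrix metrics and the leakage-safe repeated cross-validation
harness.

Within every training fold the duplicate-column removal, min-max scaler,
F-test selection and SMOTE are refitted on the training rows only; held-out
rows are transformed with those states and never enter any ``fit`` call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import descriptors as _desc
from . import ensemble as _ens
from .ensemble import PipelineConfig
from .labeling import LabeledDataset

__all__ = [
    "confusion_matrix",
    "macro_metrics",
    "CVReport",
    "repeated_cv",
]

METRIC_NAMES = ("accuracy", "macro_recall", "macro_precision", "macro_f1")


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
) -> np.ndarray:
    """g x g integer matrix, rows = true class, columns = predicted class."""
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        cm[index[t], index[p]] += 1
    return cm


def macro_metrics(cm: np.ndarray) -> dict[str, float]:
    """Accuracy and macro-averaged recall, precision and F1.

    Per class (one-vs-rest): recall = TP/(TP+FN), precision = TP/(TP+FP),
    F1 = harmonic mean; a zero denominator yields 0 for that class. Macro =
    unweighted mean over classes.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return {
        "accuracy": float(tp.sum() / total),
        "macro_recall": float(recall.mean()),
        "macro_precision": float(precision.mean()),
        "macro_f1": float(f1.mean()),
    }


@dataclass
class CVReport:
    """Per-fold metric rows plus aggregate mean/SD and the seeds used."""

    rows: list[dict]
    aggregate: dict[str, dict[str, float]]
    folds: int
    iterations: int
    base_seed: int
    task: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, tsv_path: str | Path, json_path: str | Path) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        Path(json_path).write_text(
            json.dumps(
                {
                    "task": self.task,
                    "folds": self.folds,
                    "iterations": self.iterations,
                    "base_seed": self.base_seed,
                    "aggregate": self.aggregate,
                },
                indent=2,
            )
        )


def repeated_cv(
    dataset: LabeledDataset,
    task: str,
    pipeline: PipelineConfig | None = None,
    folds: int = 6,
    iterations: int = 100,
    base_seed: int = 0,
    stratified: bool = True,
) -> CVReport:
    """Repeated k-fold cross-validation with in-fold preprocessing.

    Per iteration the data are shuffled with an iteration-specific seed and
    split into ``folds`` parts (stratified by default); per fold the whole
    training pipeline is fitted on the training part only and evaluated on
    the held-out part. The aggregate is the mean/SD over all fold cells.
    """
    pipeline = pipeline or PipelineConfig()
    records, labels = dataset.task_subset(task)
    if not records:
        raise ValueError(f"no records carry a {task} optimum")
    classes = sorted(set(labels))
    counts = {c: labels.count(c) for c in classes}
    too_small = [c for c, n in counts.items() if n < folds]
    if too_small:
        raise ValueError(
            f"classes with fewer members than folds={folds}: {too_small}"
        )
    features = _desc.featurize(records, pipeline.descriptor)
    y = np.asarray(labels, dtype=object)
    rows: list[dict] = []
    for it in range(iterations):
        seed = base_seed + it
        splitter = (
            StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            if stratified
            else KFold(n_splits=folds, shuffle=True, random_state=seed)
        )
        for fold, (train_idx, test_idx) in enumerate(splitter.split(features.data, y)):
            bundle = _ens.train_model(
                features.take_rows(train_idx),
                [labels[i] for i in train_idx],
                task=task,
                pipeline=pipeline,
                seed=seed * folds + fold,
            )
            preds = _ens.predict_matrix(bundle, features.take_rows(test_idx))
            cm = confusion_matrix(
                [labels[i] for i in test_idx], [p.label for p in preds], classes
            )
            metrics = macro_metrics(cm)
            rows.append(
                {
                    "iteration": it,
                    "fold": fold,
                    "seed": seed,
                    "k": bundle.selection.k,
                    **metrics,
                }
            )
    frame = pd.DataFrame(rows)
    aggregate = {
        name: {"mean": float(frame[name].mean()), "sd": float(frame[name].std(ddof=1))}
        for name in METRIC_NAMES
    }
    return CVReport(rows, aggregate, folds, iterations, base_seed, task)
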