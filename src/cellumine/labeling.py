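"""Optimum-value labeling and class balancing.

Measured temperature/pH optima are converted to three-way class labels;
imbalanced training folds are balanced with a from-scratch SMOTE
(interpolation between a minority point and one of its k nearest same-class
neighbours).

Boundary convention: each upper class owns its lower bound, i.e. the
temperature classes are [0, 50), [50, 75), [75, inf) and the pH classes are
[0, 5), [5, 8), [8, 14].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import FeatureMatrix
from .seqio import ProteinRecord

TEMPERATURE_CLASSES = ("mesophilic", "thermophilic", "hyperthermophilic")
PH_CLASSES = ("acidic", "neutral", "alkaline")
TASKS = ("temperature", "ph")

__all__ = [
    "TEMPERATURE_CLASSES",
    "PH_CLASSES",
    "TASKS",
    "OptimaRecord",
    "LabeledDataset",
    "label_temperature",
    "label_ph",
    "classes_for_task",
    "smote_resample",
    "read_label_table",
    "write_label_table",
]


def label_temperature(t_opt: float) -> str:
    """Map an optimum temperature (degrees C) to its class."""
    if not math.isfinite(t_opt):
        raise ValueError("t_opt must be finite")
    if t_opt < 50:
        return "mesophilic"
    if t_opt < 75:
        return "thermophilic"
    return "hyperthermophilic"


def label_ph(ph_opt: float) -> str:
    """Map an optimum pH to its class."""
    if not (0 <= ph_opt <= 14):
        raise ValueError(f"pH optimum {ph_opt} outside [0, 14]")
    if ph_opt < 5:
        return "acidic"
    if ph_opt < 8:
        return "neutral"
    return "alkaline"


def classes_for_task(task: str) -> tuple[str, ...]:
    if task == "temperature":
        return TEMPERATURE_CLASSES
    if task == "ph":
        return PH_CLASSES
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


@dataclass(frozen=True)
class OptimaRecord:
    """Measured optima for one sequence; at least one must be present."""

    id: str
    t_opt: float | None = None
    ph_opt: float | None = None

    def __post_init__(self) -> None:
        if self.t_opt is None and self.ph_opt is None:
            raise ValueError(f"record {self.id!r} has neither optimum")
        if self.t_opt is not None and not (0 <= self.t_opt <= 130):
            raise ValueError(f"record {self.id!r}: t_opt {self.t_opt} outside [0, 130]")
        if self.ph_opt is not None and not (0 <= self.ph_opt <= 14):
            raise ValueError(f"record {self.id!r}: ph_opt {self.ph_opt} outside [0, 14]")


@dataclass
class LabeledDataset:
    """Protein records with their optima and derived class labels."""

    records: list[ProteinRecord]
    optima: dict[str, OptimaRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids")
        missing = [i for i in ids if i not in self.optima]
        if missing:
            raise ValueError(f"records without optima entries: {missing}")

    def task_subset(self, task: str) -> tuple[list[ProteinRecord], list[str]]:
        """Records that carry the requested optimum, with their labels."""
        classes_for_task(task)
        records: list[ProteinRecord] = []
        labels: list[str] = []
        for rec in self.records:
            opt = self.optima[rec.id]
            if task == "temperature" and opt.t_opt is not None:
                records.append(rec)
                labels.append(label_temperature(opt.t_opt))
            elif task == "ph" and opt.ph_opt is not None:
                records.append(rec)
                labels.append(label_ph(opt.ph_opt))
        return records, labels


def read_label_table(path: str | Path) -> dict[str, OptimaRecord]:
    """Read a TSV with columns id, t_opt, ph_opt (blank cells allowed)."""
    frame = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "t_opt", "ph_opt"}
    if not required.issubset(frame.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    out: dict[str, OptimaRecord] = {}
    for row in frame.itertuples(index=False):
        t = None if pd.isna(row.t_opt) else float(row.t_opt)
        p = None if pd.isna(row.ph_opt) else float(row.ph_opt)
        out[row.id] = OptimaRecord(row.id, t, p)
    return out


def write_label_table(optima: Mapping[str, OptimaRecord], path: str | Path) -> None:
    rows = [
        {"id": o.id, "t_opt": o.t_opt, "ph_opt": o.ph_opt} for o in optima.values()
    ]
    pd.DataFrame(rows, columns=["id", "t_opt", "ph_opt"]).to_csv(
        path, sep="\t", index=False
    )


def smote_resample(
    features: FeatureMatrix,
    labels: Sequence[str],
    k: int = 5,
    seed: int = 0,
) -> tuple[FeatureMatrix, list[str]]:
    """Oversample minority classes to exact parity with the majority class.

    Each synthetic row is ``x + u * (neighbour - x)`` where ``x`` is a
    uniformly chosen minority row, ``neighbour`` one of its k nearest
    same-class rows (Euclidean; effective k = min(k, class size - 1)) and
    ``u ~ Uniform(0, 1)``. Original rows are preserved in order; synthetic
    rows are appended with generated ids.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = list(labels)
    if len(labels) != features.shape[0]:
        raise ValueError("labels length does not match feature rows")
    counts: dict[str, int] = {}
    for lbl in labels:
        counts[lbl] = counts.get(lbl, 0) + 1
    singletons = sorted(c for c, n in counts.items() if n == 1)
    if singletons:
        raise ValueError(
            f"classes with a single member cannot be oversampled or trained: "
            f"{singletons}; collect more data or drop them"
        )
    rng = np.random.default_rng(seed)
    majority = max(counts.values())
    new_rows: list[np.ndarray] = []
    new_ids: list[str] = []
    new_labels: list[str] = []
    for cls in sorted(counts):  # sorted for seed-stable iteration order
        need = majority - counts[cls]
        if need == 0:
            continue
        rows = np.flatnonzero(np.asarray(labels, dtype=object) == cls)
        x = features.data[rows]
        k_eff = min(k, len(rows) - 1)
        # k nearest same-class neighbours, self excluded
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        neighbours = np.argsort(d2, axis=1, kind="stable")[:, :k_eff]
        for s in range(need):
            i = int(rng.integers(len(rows)))
            j = int(neighbours[i, int(rng.integers(k_eff))])
            u = float(rng.uniform())
            new_rows.append(x[i] + u * (x[j] - x[i]))
            new_ids.append(f"synthetic_{cls}_{s + 1}")
            new_labels.append(cls)
    if not new_rows:
        return features, labels
    data = np.vstack([features.data, np.array(new_rows)])
    out = FeatureMatrix(
        features.ids + new_ids,
        list(features.columns),
        data,
        features.provenance
        + [{
            "op": "smote",
            "seed": seed,
            "k": k,
            "before": counts,
            "after": {c: majority for c in counts},
        }],
    )
    return out, labels + new_labels
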