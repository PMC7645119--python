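"""Soft-voting ensemble of MLP, random forest and RBF-kernel SVM.

``train_model`` runs the full training-fold pipeline (duplicate-column
removal, min-max scaling, F-test selection, SMOTE, classifier fitting) and
returns a serializable :class:`ModelBundle`; ``predict`` maps raw protein
records through the bundle's recorded preprocessing to weighted-soft-vote
class probabilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import descriptors as _desc
from . import labeling as _lab
from . import selection as _sel
from .descriptors import DescriptorConfig, FeatureMatrix, ScalerState
from .seqio import ProteinRecord
from .selection import SelectionState

__all__ = [
    "EnsembleConfig",
    "PipelineConfig",
    "ModelBundle",
    "PredictionResult",
    "fit_ensemble",
    "train_model",
    "soft_vote",
    "predict",
    "predict_matrix",
    "save_bundle",
    "load_bundle",
]

BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of the three base classifiers and the vote weights."""

    mlp_hidden: tuple[int, int] = (200, 200)
    mlp_max_iter: int = 500
    mlp_early_stopping: bool = True
    mlp_validation_fraction: float = 0.1
    rf_trees: int = 200
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    vote_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        if any(w < 0 for w in self.vote_weights) or sum(self.vote_weights) <= 0:
            raise ValueError("vote weights must be non-negative and sum > 0")

    def to_dict(self) -> dict:
        return {
            "mlp_hidden": list(self.mlp_hidden),
            "mlp_max_iter": self.mlp_max_iter,
            "mlp_early_stopping": self.mlp_early_stopping,
            "mlp_validation_fraction": self.mlp_validation_fraction,
            "rf_trees": self.rf_trees,
            "svm_c": self.svm_c,
            "svm_gamma": self.svm_gamma,
            "vote_weights": list(self.vote_weights),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EnsembleConfig":
        return cls(
            tuple(d["mlp_hidden"]), int(d["mlp_max_iter"]),
            bool(d["mlp_early_stopping"]), float(d["mlp_validation_fraction"]),
            int(d["rf_trees"]), float(d["svm_c"]), d["svm_gamma"],
            tuple(d["vote_weights"]),
        )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end training configuration shared by train/evaluate commands."""

    descriptor: DescriptorConfig = field(default_factory=DescriptorConfig)
    k: int | str = "auto"
    alpha: float = 0.05
    smote_k: int = 5
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)

    def to_dict(self) -> dict:
        return {
            "descriptor": self.descriptor.to_dict(),
            "k": self.k,
            "alpha": self.alpha,
            "smote_k": self.smote_k,
            "ensemble": self.ensemble.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(
            DescriptorConfig.from_dict(d["descriptor"]),
            d["k"], float(d["alpha"]), int(d["smote_k"]),
            EnsembleConfig.from_dict(d["ensemble"]),
        )


MODEL_ORDER = ("mlp", "rf", "svm")


@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: preprocessing states,
    the three fitted classifiers, vote weights and seeds."""

    task: str
    classes: tuple[str, ...]
    columns: list[str]  # post-dedup training column set, pre-selection
    scaler: ScalerState | None
    selection: SelectionState | None
    models: dict
    vote_weights: tuple[float, float, float]
    config: EnsembleConfig
    descriptor_config: DescriptorConfig
    seed: int

    def model_classes(self) -> np.ndarray:
        return self.models["mlp"].classes_


def _build_models(config: EnsembleConfig, seed: int, n_rows: int) -> dict:
    early = config.mlp_early_stopping and n_rows >= 20
    return {
        "mlp": MLPClassifier(
            hidden_layer_sizes=config.mlp_hidden,
            activation="relu",
            solver="adam",
            max_iter=config.mlp_max_iter,
            early_stopping=early,
            validation_fraction=config.mlp_validation_fraction,
            random_state=seed,
        ),
        "rf": RandomForestClassifier(
            n_estimators=config.rf_trees,
            criterion="entropy",  # information-gain splitting
            random_state=seed,
        ),
        "svm": SVC(
            kernel="rbf",
            C=config.svm_c,
            gamma=config.svm_gamma,
            probability=True,  # Platt-style sigmoid calibration
            random_state=seed,
        ),
    }


def fit_ensemble(
    train: FeatureMatrix,
    labels: Sequence[str],
    config: EnsembleConfig | None = None,
    seed: int = 0,
    *,
    task: str = "temperature",
    scaler: ScalerState | None = None,
    selection: SelectionState | None = None,
    columns: Sequence[str] | None = None,
    descriptor_config: DescriptorConfig | None = None,
) -> ModelBundle:
    """Fit the three base classifiers on identical (already preprocessed)
    data and assemble a bundle. Deterministic given ``seed``."""
    config = config or EnsembleConfig()
    labels = list(labels)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit the ensemble")
    if train.shape[0] < 6:
        raise ValueError("need at least 6 training rows")
    if not np.all(np.isfinite(train.data)):
        raise ValueError("non-finite feature values")
    models = _build_models(config, seed, train.shape[0])
    y = np.asarray(labels, dtype=object)
    with warnings.catch_warnings():
        # SVC(probability=True) is the intended Platt-style calibration;
        # sklearn 1.9 deprecates the flag in favour of CalibratedClassifierCV
        warnings.filterwarnings("ignore", category=FutureWarning)
        for model in models.values():
            model.fit(train.data, y)
    return ModelBundle(
        task=task,
        classes=classes,
        columns=list(columns) if columns is not None else list(train.columns),
        scaler=scaler,
        selection=selection,
        models=models,
        vote_weights=config.vote_weights,
        config=config,
        descriptor_config=descriptor_config or DescriptorConfig(),
        seed=seed,
    )


def train_model(
    features: FeatureMatrix,
    labels: Sequence[str],
    *,
    task: str,
    pipeline: PipelineConfig | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Training-fold pipeline: dedup -> scale -> select -> SMOTE -> fit.

    ``features`` are raw (unscaled) descriptor values for the training rows
    only; every state is fitted on them alone.
    """
    pipeline = pipeline or PipelineConfig()
    m = _desc.drop_duplicate_columns(features)
    columns = list(m.columns)
    scaler = _desc.fit_scaler(m)
    m = _desc.apply_scaler(scaler, m)
    selection = _sel.select_k_best(m, labels, pipeline.k, pipeline.alpha)
    m = _sel.apply_selection(selection, m)
    m, labels = _lab.smote_resample(m, labels, k=pipeline.smote_k, seed=seed)
    return fit_ensemble(
        m, labels, pipeline.ensemble, seed,
        task=task, scaler=scaler, selection=selection, columns=columns,
        descriptor_config=pipeline.descriptor,
    )


def soft_vote(
    probas: Sequence[Sequence[float]], weights: Sequence[float]
) -> tuple[int, np.ndarray]:
    """Weighted average of per-model probability vectors.

    Returns (argmax class index, combined vector); ties resolve to the
    lowest class index. Invariant to uniform rescaling of weights.
    """
    P = np.asarray(probas, dtype=float)
    w = np.asarray(weights, dtype=float)
    if P.ndim != 2 or len(w) != P.shape[0]:
        raise ValueError("need one weight per probability vector")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("each probability vector must sum to 1")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    combined = (w[:, None] * P).sum(axis=0) / w.sum()
    return int(np.argmax(combined)), combined


@dataclass(frozen=True)
class PredictionResult:
    id: str
    label: str | None
    probabilities: dict | None  # class -> combined probability
    per_model: dict | None  # model name -> {class: probability}
    error: str | None = None


def predict_matrix(bundle: ModelBundle, features: FeatureMatrix) -> list[PredictionResult]:
    """Run already-featurized rows through projection, scaling, selection
    and the weighted soft vote."""
    m = _desc.project_columns(features, bundle.columns)
    if bundle.scaler is not None:
        m = _desc.apply_scaler(bundle.scaler, m)
    if bundle.selection is not None:
        m = _sel.apply_selection(bundle.selection, m)
    classes = list(bundle.model_classes())
    per_model_probas = {
        name: bundle.models[name].predict_proba(m.data) for name in MODEL_ORDER
    }
    results: list[PredictionResult] = []
    for i, rec_id in enumerate(m.ids):
        stacked = [per_model_probas[name][i] for name in MODEL_ORDER]
        idx, combined = soft_vote(stacked, bundle.vote_weights)
        results.append(
            PredictionResult(
                id=rec_id,
                label=str(classes[idx]),
                probabilities={str(c): float(p) for c, p in zip(classes, combined)},
                per_model={
                    name: {str(c): float(p) for c, p in zip(classes, per_model_probas[name][i])}
                    for name in MODEL_ORDER
                },
            )
        )
    return results


def predict(bundle: ModelBundle, records: Sequence[ProteinRecord]) -> list[PredictionResult]:
    """Predict class labels and probabilities for raw protein records.

    Records too short for the bundle's descriptor blocks get a per-record
    error entry; the rest are processed normally. Output order = input order.
    """
    min_len = bundle.descriptor_config.min_sequence_length()
    valid = [r for r in records if len(r.seq) >= min_len]
    by_id: dict[str, PredictionResult] = {}
    if valid:
        features = _desc.featurize(valid, bundle.descriptor_config)
        for res in predict_matrix(bundle, features):
            by_id[res.id] = res
    out = []
    for rec in records:
        if rec.id in by_id:
            out.append(by_id[rec.id])
        else:
            out.append(
                PredictionResult(
                    rec.id, None, None, None,
                    error=f"sequence length {len(rec.seq)} below descriptor "
                          f"minimum {min_len}",
                )
            )
    return out


def predictions_to_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    """TSV-ready table: id, predicted label, per-class probabilities."""
    classes: list[str] = []
    for r in results:
        if r.probabilities:
            classes = list(r.probabilities)
            break
    rows = []
    for r in results:
        row: dict = {"id": r.id, "predicted_label": r.label or "ERROR"}
        for c in classes:
            row[f"p_{c}"] = r.probabilities[c] if r.probabilities else np.nan
        row["error"] = r.error or ""
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization: metadata JSON + joblib model blobs in one directory
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "task": bundle.task,
        "classes": list(bundle.classes),
        "columns": bundle.columns,
        "scaler": bundle.scaler.to_dict() if bundle.scaler else None,
        "selection": bundle.selection.to_dict() if bundle.selection else None,
        "vote_weights": list(bundle.vote_weights),
        "config": bundle.config.to_dict(),
        "descriptor_config": bundle.descriptor_config.to_dict(),
        "seed": bundle.seed,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(bundle.models, path / "models.joblib")


def load_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no bundle metadata at {meta_path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported bundle format {meta.get('format_version')}")
    models = joblib.load(path / "models.joblib")
    return ModelBundle(
        task=meta["task"],
        classes=tuple(meta["classes"]),
        columns=list(meta["columns"]),
        scaler=ScalerState.from_dict(meta["scaler"]) if meta["scaler"] else None,
        selection=(
            SelectionState.from_dict(meta["selection"]) if meta["selection"] else None
        ),
        models=models,
        vote_weights=tuple(meta["vote_weights"]),
        config=EnsembleConfig.from_dict(meta["config"]),
        descriptor_config=DescriptorConfig.from_dict(meta["descriptor_config"]),
        seed=int(meta["seed"]),
    )
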