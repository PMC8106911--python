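"""The random-forest lifestyle model: fit, persist, predict.

The classifier consumes a binary presence/absence vector over a fixed
ordered domain set and outputs the probability of each lifestyle.  The
default hyperparameters are the selected final configuration of the
model-development protocol (see :mod:`lysotyper.model_dev`).

The decision rule embodies a virulent prior: an input genome is assumed
virulent unless domain evidence pushes p(temperate) strictly above 0.5,
so an exact tie is called virulent.  Predictions with max probability
>= the confidence threshold (default 0.95, inclusive) are flagged
confident.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .domain_search import DomainSet, PresenceVector
from .feature_table import LabeledDataset, TEMPERATE, VIRULENT

MODEL_FORMAT_VERSION = "lysotyper-model-1"


@dataclass(frozen=True)
class Hyperparameters:
    """Random-forest settings; defaults are the selected final model."""

    bootstrap: bool = False
    class_weight: str = "balanced_subsample"
    min_samples_leaf: int = 1
    n_estimators: int = 80
    max_depth: int = 40
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1 or self.min_samples_leaf < 1:
            raise ValueError("n_estimators, max_depth, min_samples_leaf must be >= 1")
        if self.class_weight not in ("balanced", "balanced_subsample"):
            raise ValueError("class_weight must be 'balanced' or 'balanced_subsample'")


@dataclass(frozen=True)
class LifestyleModel:
    forest: RandomForestClassifier
    domain_set: DomainSet
    hyperparameters: Hyperparameters
    training_fingerprint: str
    format_version: str = MODEL_FORMAT_VERSION


@dataclass(frozen=True)
class PredictionResult:
    genome_id: str
    p_virulent: float
    p_temperate: float
    call: str
    confident: bool


def classify_probability(
    p_temperate: float, confidence_threshold: float = 0.95
) -> tuple[str, bool]:
    """Decision rule: temperate iff p(temperate) > 0.5 (tie -> virulent);
    confident iff the winning probability >= threshold (inclusive)."""
    call = TEMPERATE if p_temperate > 0.5 else VIRULENT
    p_max = p_temperate if call == TEMPERATE else 1.0 - p_temperate
    return call, bool(p_max >= confidence_threshold)


def _fingerprint(dataset: LabeledDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.matrix).tobytes())
    h.update("\x00".join(dataset.labels).encode())
    h.update("\x00".join(dataset.genome_ids).encode())
    return h.hexdigest()


def fit(dataset: LabeledDataset, hp: Hyperparameters | None = None) -> LifestyleModel:
    """Train the forest; deterministic given (dataset, hp, seed).

    Requires at least two genomes per class and a strictly binary matrix
    (the feature contract is presence/absence).
    """
    hp = hp or Hyperparameters()
    labels = dataset.label_array()
    for cls in (TEMPERATE, VIRULENT):
        if (labels == cls).sum() < 2:
            raise ValueError(f"need >= 2 genomes of class {cls!r} to fit")
    forest = RandomForestClassifier(
        n_estimators=hp.n_estimators,
        max_depth=hp.max_depth,
        min_samples_leaf=hp.min_samples_leaf,
        bootstrap=hp.bootstrap,
        class_weight=hp.class_weight,
        random_state=hp.random_seed,
        n_jobs=1,
    )
    forest.fit(dataset.matrix, labels)
    return LifestyleModel(forest, dataset.domain_set, hp, _fingerprint(dataset))


def _proba_temperate(model: LifestyleModel, matrix: np.ndarray) -> np.ndarray:
    proba = model.forest.predict_proba(matrix)
    idx = list(model.forest.classes_).index(TEMPERATE)
    return proba[:, idx]


def predict(
    model: LifestyleModel,
    vector: PresenceVector,
    confidence_threshold: float = 0.95,
) -> PredictionResult:
    if len(vector) != len(model.domain_set):
        raise ValueError(
            f"feature vector length mismatch: model expects "
            f"{len(model.domain_set)}, received {len(vector)}"
        )
    p_t = float(_proba_temperate(model, vector.values.reshape(1, -1))[0])
    call, confident = classify_probability(p_t, confidence_threshold)
    return PredictionResult(vector.genome_id, 1.0 - p_t, p_t, call, confident)


def predict_many(
    model: LifestyleModel,
    vectors: Sequence[PresenceVector],
    confidence_threshold: float = 0.95,
) -> list[PredictionResult]:
    return [predict(model, v, confidence_threshold) for v in vectors]


def save_model(model: LifestyleModel, path) -> None:
    payload = {
        "format_version": model.format_version,
        "forest": model.forest,
        "domain_set": model.domain_set,
        "hyperparameters": model.hyperparameters,
        "training_fingerprint": model.training_fingerprint,
    }
    joblib.dump(payload, path)


def load_model(path) -> LifestyleModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a lysotyper model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format {payload['format_version']!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION!r})"
        )
    return LifestyleModel(
        payload["forest"],
        payload["domain_set"],
        payload["hyperparameters"],
        payload["training_fingerprint"],
        payload["format_version"],
    )


def feature_importances(model: LifestyleModel) -> pd.DataFrame:
    """Per-domain Gini importances, descending, with cumulative share.

    The cumulative_share column supports top-k summaries of how
    concentrated the model's weight is (the importance distribution is
    typically highly skewed, with a small head of domains carrying most
    of the weight).
    """
    imp = model.forest.feature_importances_
    df = pd.DataFrame(
        {"accession": list(model.domain_set.accessions), "importance": imp}
    )
    df = df.sort_values("importance", ascending=False, kind="stable").reset_index(
        drop=True
    )
    total = df["importance"].sum()
    df["cumulative_share"] = (
        df["importance"].cumsum() / total if total > 0 else np.nan
    )
    return df


def write_predictions_tsv(results: Sequence[PredictionResult], path) -> None:
    """Prediction table: genome_id, p_virulent, p_temperate, call, confident.

    Probabilities are printed with 4 decimal places.
    """
    df = pd.DataFrame(
        {
            "genome_id": [r.genome_id for r in results],
            "p_virulent": [f"{r.p_virulent:.4f}" for r in results],
            "p_temperate": [f"{r.p_temperate:.4f}" for r in results],
            "call": [r.call for r in results],
            "confident": [str(r.confident) for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
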