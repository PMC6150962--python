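"""Three-class classification of candidate complexes from complex vectors.

Each training complex becomes one row — the column-wise pooling of its member
embeddings — labelled positive / intermediate / negative.  A random forest
(1000 trees by default) is fitted on these rows; SVM (RBF) and logistic
regression comparators are available through the same interface.  Candidate
complexes predicted ``positive`` are kept as final predictions; intermediate
and negative predictions are logged and discarded.
"""

from __future__ import annotations

import json
import logging
import pickle
import warnings
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .embedding import EmbeddingMatrix, complex_vector
from .ppi_io import Complex
from .slpc import LabeledComplexSet

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "build_training_matrix",
    "train_classifier",
    "filter_candidates",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Model family and hyperparameters for candidate filtering."""

    model: str = "rf"
    n_trees: int = 1000
    seed: int = 0
    vector_strategy: str = "max"

    def __post_init__(self):
        if self.model not in ("rf", "svm", "lr"):
            raise ValueError(f"unknown model: {self.model!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.vector_strategy not in ("max", "min", "average"):
            raise ValueError(f"unknown vector strategy: {self.vector_strategy!r}")


def build_training_matrix(train: LabeledComplexSet, emb: EmbeddingMatrix,
                          strategy: str = "max") -> Tuple[np.ndarray, np.ndarray]:
    """Pool each training complex into one feature row; returns (rows, labels).

    Complexes with unembedded members are skipped with a warning; a class left
    empty (before or after skipping) is an error.
    """
    train.validate()
    rows, labels = [], []
    skipped = 0
    for cx, label in train.labeled():
        try:
            rows.append(complex_vector(cx, emb, strategy))
        except KeyError:
            skipped += 1
            continue
        labels.append(label)
    if skipped:
        warnings.warn(f"{skipped} training complexes skipped (unembedded members)")
    counts = Counter(labels)
    for cls in ("positive", "intermediate", "negative"):
        if counts.get(cls, 0) == 0:
            raise ValueError(f"training class {cls!r} is empty after embedding")
    return np.stack(rows), np.array(labels)


def train_classifier(rows: np.ndarray, labels: np.ndarray,
                     config: ClassifierConfig):
    """Fit the configured classifier on complex-vector rows."""
    rows = np.asarray(rows, dtype=float)
    labels = np.asarray(labels)
    if rows.shape[0] != labels.shape[0]:
        raise ValueError("rows/labels length mismatch")
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two classes to train")
    if config.model == "rf":
        clf = RandomForestClassifier(n_estimators=config.n_trees,
                                     random_state=config.seed)
    elif config.model == "svm":
        clf = SVC(kernel="rbf", random_state=config.seed)
    else:
        clf = LogisticRegression(max_iter=1000, random_state=config.seed)
    clf.fit(rows, labels)
    acc = float((clf.predict(rows) == labels).mean())
    logger.info("train_classifier: %s on %d samples (train accuracy %.3f)",
                config.model, len(labels), acc)
    return clf


def filter_candidates(candidates: Sequence[Complex], emb: EmbeddingMatrix,
                      model, strategy: str = "max") -> List[Complex]:
    """Keep exactly the candidates the model labels ``positive`` (order kept).

    Candidates with unembedded members are excluded with a warning.
    """
    usable, rows = [], []
    excluded = 0
    for cx in candidates:
        try:
            rows.append(complex_vector(cx, emb, strategy))
        except KeyError:
            excluded += 1
            continue
        usable.append(cx)
    if excluded:
        warnings.warn(f"{excluded} candidates excluded (unembedded members)")
    if not usable:
        return []
    predictions = model.predict(np.stack(rows))
    counts = Counter(predictions.tolist())
    logger.info("filter_candidates: predicted class counts %s", dict(counts))
    return [cx for cx, label in zip(usable, predictions) if label == "positive"]


def save_model(model, config: ClassifierConfig, path) -> None:
    """Persist the fitted model (pickle) with a JSON sidecar of its config."""
    path = Path(path)
    with path.open("wb") as fh:
        pickle.dump(model, fh)
    with path.with_suffix(path.suffix + ".json").open("w") as fh:
        json.dump(asdict(config), fh, indent=2)


def load_model(path):
    path = Path(path)
    with path.open("rb") as fh:
        model = pickle.load(fh)
    sidecar = path.with_suffix(path.suffix + ".json")
    config = None
    if sidecar.exists():
        with sidecar.open() as fh:
            config = ClassifierConfig(**json.load(fh))
    return model, config
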