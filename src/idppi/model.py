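"""Classifier training and prediction over 940-dimensional pair vectors.

Four classifier families are supported — random forest, gradient
boosting, a regularized linear model, and an RBF/linear SVM — all via
scikit-learn, with optional grid or random hyperparameter search scored
by inner cross-validated AUC. A trained model remembers its feature
schema and a training fingerprint and refuses to score vectors produced
under a different schema.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np

from .datasets import InteractionDataset
from .errors import ConfigurationError, SchemaMismatchError
from .features import PaacConfig, pair_matrix, pair_schema
from .sequences import ProteinSequence

ALGORITHMS = ("random_forest", "gradient_boosting", "linear_model", "svm")

#: Documented defaults per family; anything can be overridden through
#: ClassifierSpec.hyperparameters or tuned through the search space.
DEFAULT_HYPERPARAMETERS = {
    "random_forest": {"n_estimators": 500, "max_features": "sqrt"},
    "gradient_boosting": {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 3},
    "linear_model": {"C": 1.0, "max_iter": 2000},
    "svm": {"C": 1.0, "gamma": "scale", "kernel": "rbf"},
}


@dataclass(frozen=True)
class ClassifierSpec:
    algorithm: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    search: str = "none"
    search_space: dict = field(default_factory=dict)
    n_search_iter: int = 10
    inner_cv: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )
        if self.search not in ("none", "grid", "random"):
            raise ConfigurationError(f"search must be none/grid/random, got {self.search!r}")
        if self.search != "none" and not self.search_space:
            raise ConfigurationError(f"search={self.search!r} requires a non-empty search_space")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    feature_schema: tuple[str, ...]
    training_fingerprint: str


def _build_estimator(spec: ClassifierSpec):
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    params = {**DEFAULT_HYPERPARAMETERS[spec.algorithm], **spec.hyperparameters}
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.algorithm == "gradient_boosting":
        # greedy (non-histogram) boosting: it still splits when no single
        # feature has marginal gain, which degree-balanced training sets
        # produce by construction
        return GradientBoostingClassifier(random_state=spec.seed, **params)
    if spec.algorithm == "linear_model":
        return make_pipeline(
            StandardScaler(), LogisticRegression(random_state=spec.seed, **params)
        )
    # SVC scores come from the decision function mapped through a logistic
    # (Platt-style probability calibration is unstable on small samples)
    return make_pipeline(StandardScaler(), SVC(random_state=spec.seed, **params))


def _maybe_search(estimator, spec: ClassifierSpec):
    from sklearn.model_selection import (
        GridSearchCV,
        RandomizedSearchCV,
        StratifiedKFold,
    )

    if spec.search == "none":
        return estimator
    cv = StratifiedKFold(n_splits=spec.inner_cv, shuffle=True, random_state=spec.seed)
    if spec.search == "grid":
        return GridSearchCV(estimator, spec.search_space, scoring="roc_auc", cv=cv, n_jobs=1)
    return RandomizedSearchCV(
        estimator,
        spec.search_space,
        n_iter=spec.n_search_iter,
        scoring="roc_auc",
        cv=cv,
        random_state=spec.seed,
        n_jobs=1,
    )


def _fingerprint(dataset: InteractionDataset, spec: ClassifierSpec) -> str:
    h = hashlib.sha256()
    for rec in sorted(dataset.records, key=lambda r: r.key):
        h.update(f"{rec.idp_id}\t{rec.partner_id}\t{rec.label}\n".encode())
    h.update(f"seed={spec.seed};algo={spec.algorithm}".encode())
    return h.hexdigest()[:16]


def train(
    train_set: InteractionDataset, cfg: PaacConfig, spec: ClassifierSpec
) -> TrainedModel:
    """Encode all pairs and fit the requested classifier.

    Raises on a single-class training set. Deterministic under a fixed
    seed for the tree and linear families; SVC probability calibration is
    seeded but solver-tolerance sensitive.
    """
    labels = np.array([r.label for r in train_set.records])
    if labels.size == 0 or labels.min() == labels.max():
        raise ValueError("training set must contain both positive and negative pairs")
    X = pair_matrix(
        [r.key for r in train_set.records], train_set.sequence_store, cfg
    ).to_numpy()
    estimator = _maybe_search(_build_estimator(spec), spec)
    estimator.fit(X, labels)
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        feature_schema=pair_schema(cfg.lambda_tiers),
        training_fingerprint=_fingerprint(train_set, spec),
    )


def _positive_scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        pos_col = list(estimator.classes_).index(1)
        return proba[:, pos_col]
    margin = estimator.decision_function(X)
    if list(estimator.classes_) != [0, 1]:
        margin = -margin
    return 1.0 / (1.0 + np.exp(-margin))


def predict(
    model: TrainedModel,
    pairs: Sequence[tuple[ProteinSequence, ProteinSequence]],
    cfg: PaacConfig,
) -> np.ndarray:
    """Score (idp, partner) sequence pairs; one probability per pair, in order."""
    if pair_schema(cfg.lambda_tiers) != model.feature_schema:
        raise SchemaMismatchError(
            "feature schema at predict time differs from the schema the model was fit with"
        )
    store = {s.id: s for pair in pairs for s in pair}
    keys = [(a.id, b.id) for a, b in pairs]
    X = pair_matrix(keys, store, cfg).to_numpy()
    return _positive_scores(model.estimator, X)


def predict_dataset(
    model: TrainedModel, dataset: InteractionDataset, cfg: PaacConfig
) -> np.ndarray:
    """Score every record of a dataset, preserving record order."""
    if pair_schema(cfg.lambda_tiers) != model.feature_schema:
        raise SchemaMismatchError(
            "feature schema at predict time differs from the schema the model was fit with"
        )
    X = pair_matrix(
        [r.key for r in dataset.records], dataset.sequence_store, cfg
    ).to_numpy()
    return _positive_scores(model.estimator, X)


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (estimator + schema + fingerprint) to one file."""
    joblib.dump(
        {
            "spec": model.spec,
            "estimator": model.estimator,
            "feature_schema": model.feature_schema,
            "training_fingerprint": model.training_fingerprint,
        },
        path,
    )


def load_model(path, expected_schema: tuple[str, ...] | None = None) -> TrainedModel:
    """Load a persisted model; refuses a mismatched feature schema."""
    payload = joblib.load(path)
    if expected_schema is not None and tuple(payload["feature_schema"]) != tuple(expected_schema):
        raise SchemaMismatchError(f"model at {path} was fit under a different feature schema")
    return TrainedModel(
        spec=payload["spec"],
        estimator=payload["estimator"],
        feature_schema=tuple(payload["feature_schema"]),
        training_fingerprint=payload["training_fingerprint"],
    )
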