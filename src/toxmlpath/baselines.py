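"""Traditional multi-label baselines: binary relevance, classifier chains,
and a per-label 5-nearest-neighbour model.

Binary relevance (BR) trains one independent binary classifier per label.
Classifier chains (CC) extend BR: the j-th classifier additionally sees the
preceding j-1 labels — true labels at training time, predicted labels at
prediction time — so downstream classifiers can exploit label correlation.
Base learners are injected via a factory (any sklearn-style estimator with
``fit`` and a probability-like ``score``); common choices are logistic
regression, random forest and linear SVM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .datamodel import ValidationError

log = logging.getLogger(__name__)


class _ConstantLearner:
    """Fallback when a label is single-class in training data."""

    def __init__(self, value: float):
        self.value = float(value)

    def fit(self, X, y):
        return self

    def score_samples(self, X):
        return np.full(len(X), self.value)


def _fit_one(learner, X, y):
    y = np.asarray(y)
    if y.min() == y.max():
        log.warning("single-class label (all %d); using constant predictor", int(y[0]))
        return _ConstantLearner(float(y[0]))
    learner.fit(X, y)
    return learner


def _score_one(model, X) -> np.ndarray:
    """Probability-like score for the positive class, in [0, 1]."""
    if isinstance(model, _ConstantLearner):
        return model.score_samples(X)
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        return proba[:, list(model.classes_).index(1)]
    if hasattr(model, "decision_function"):
        d = model.decision_function(X)
        return 1.0 / (1.0 + np.exp(-np.clip(d, -500, 500)))
    return np.asarray(model.predict(X), dtype=float)


@dataclass
class BinaryRelevanceModel:
    models: list
    threshold: float = 0.5

    def predict_scores(self, X) -> np.ndarray:
        return np.column_stack([_score_one(m, X) for m in self.models])

    def predict(self, X) -> np.ndarray:
        return (self.predict_scores(X) >= self.threshold).astype(np.int64)


def binary_relevance_train(features, labels, learner_factory: Callable[[], object]) -> BinaryRelevanceModel:
    """One independent base learner per label."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    models = [_fit_one(learner_factory(), features, labels[:, l]) for l in range(labels.shape[1])]
    return BinaryRelevanceModel(models)


@dataclass
class ClassifierChainModel:
    models: list
    order: list[int]
    threshold: float = 0.5

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        L = len(self.order)
        scores = np.zeros((n, L))
        preds = np.zeros((n, L))
        chain_feats = X
        for j, lab in enumerate(self.order):
            s = _score_one(self.models[j], chain_feats)
            scores[:, lab] = s
            preds[:, lab] = (s >= self.threshold).astype(float)
            chain_feats = np.column_stack([chain_feats, preds[:, lab]])
        return scores

    def predict(self, X) -> np.ndarray:
        return (self.predict_scores(X) >= self.threshold).astype(np.int64)


def classifier_chain_train(
    features,
    labels,
    order: Sequence[int] | None = None,
    learner_factory: Callable[[], object] | None = None,
) -> ClassifierChainModel:
    """Chain of binary learners; j-th trained on features + true preceding labels."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    L = labels.shape[1]
    if order is None:
        order = list(range(L))
    order = list(order)
    if sorted(order) != list(range(L)):
        raise ValidationError(f"order must be a permutation of 0..{L - 1}")
    if learner_factory is None:
        raise ValidationError("learner_factory is required")
    models = []
    chain_feats = features
    for j, lab in enumerate(order):
        models.append(_fit_one(learner_factory(), chain_feats, labels[:, lab]))
        chain_feats = np.column_stack([chain_feats, labels[:, lab]])
    return ClassifierChainModel(models, order)


@dataclass
class KnnPerLabelModel:
    train_features: np.ndarray
    train_labels: np.ndarray
    k: int = 5

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(X[:, None, :] - self.train_features[None, :, :], axis=2)
        nn = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        votes = self.train_labels[nn].mean(axis=1)  # (n_query, L) positive fraction
        return votes

    def predict(self, X) -> np.ndarray:
        # ties (exactly half the neighbours positive) predict positive
        return (self.predict_scores(X) >= 0.5).astype(np.int64)


def knn_per_label_train(features, labels, k: int = 5) -> KnnPerLabelModel:
    """Per-label majority vote of the k Euclidean nearest training samples."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[0] <= k:
        raise ValidationError(f"need more than k={k} training samples, got {features.shape[0]}")
    return KnnPerLabelModel(features.copy(), labels.copy(), k)


def make_base_learner(name: str, seed: int = 0) -> Callable[[], object]:
    """Factory for the standard injected base learners: lr / rf / svm."""
    def factory():
        if name == "lr":
            from sklearn.linear_model import LogisticRegression
            return LogisticRegression(max_iter=1000, random_state=seed)
        if name == "rf":
            from sklearn.ensemble import RandomForestClassifier
            return RandomForestClassifier(n_estimators=100, random_state=seed)
        if name == "svm":
            from sklearn.svm import LinearSVC
            return LinearSVC(random_state=seed)
        raise ValidationError(f"unknown base learner {name!r}; expected lr, rf or svm")
    factory()  # fail fast on bad names
    return factory
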