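"""Hybrid deep-encoder + classical-head classifier and majority voting.

The hybrid pairs an encoder (transformer or autoencoder) with a
grid-searched classical head. Training is two-phase: the encoder is fitted
on the training features (supervised through a temporary softmax head for
the transformer, unsupervised for the autoencoder), then frozen; the head
is grid-search-fitted on the encoder's latents. Prediction is exactly
``head.predict(encoder.transform(x))``.

:func:`bagging_combine` is the generic bootstrap-aggregation combiner:
majority vote for classification (ties broken toward the lower label, a
documented deterministic rule) and the member mean for regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError, InputError
from .models import (
    Autoencoder,
    ClassifierSpec,
    FittedClassifier,
    TransformerEncoder,
    grid_search_fit,
)
from .preprocessing import FeatureMatrix

ENCODERS = {"transformer": TransformerEncoder, "autoencoder": Autoencoder}


@dataclass
class HybridSpec:
    """Configuration of an encoder → classical head pairing."""

    encoder: str = "transformer"
    head: str = "rf"
    encoder_params: Mapping[str, Any] = field(default_factory=dict)
    head_grid: Mapping[str, list] = field(default_factory=dict)
    cv_folds: int = 4

    def __post_init__(self) -> None:
        if self.encoder not in ENCODERS:
            raise ConfigError(
                f"unknown encoder {self.encoder!r}; registered: {sorted(ENCODERS)}"
            )


class HybridClassifier(BaseEstimator, ClassifierMixin):
    """Deep encoder with a grid-searched classical classifier head.

    Parameters mirror :class:`HybridSpec`; the default pairing is the
    best-performing one for this task (transformer encoder, random-forest
    head).
    """

    def __init__(
        self,
        encoder: str = "transformer",
        head: str = "rf",
        encoder_params: Mapping[str, Any] | None = None,
        head_grid: Mapping[str, list] | None = None,
        cv_folds: int = 4,
        random_state: int = 0,
    ):
        self.encoder = encoder
        self.head = head
        self.encoder_params = encoder_params
        self.head_grid = head_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise InputError("hybrid training needs at least two classes")
        if self.encoder not in ENCODERS:
            raise ConfigError(f"unknown encoder {self.encoder!r}")
        params = dict(self.encoder_params or {})
        params.setdefault("random_state", self.random_state)
        enc = ENCODERS[self.encoder](**params)
        if self.encoder == "transformer":
            enc.fit(X, y)
        else:
            enc.fit(X)
        self.encoder_ = enc
        latents = enc.transform(X)
        spec = ClassifierSpec(
            self.head,
            dict(self.head_grid or {}),
            cv_folds=self.cv_folds,
        )
        self.head_: FittedClassifier = grid_search_fit(
            spec, (latents, y), seed=self.random_state
        )
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "head_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.head_.predict(self.encoder_.transform(X))


def fit_hybrid(
    spec: HybridSpec, train: FeatureMatrix, seed: int = 0
) -> HybridClassifier:
    """Functional wrapper over :class:`HybridClassifier` for FeatureMatrix."""
    model = HybridClassifier(
        encoder=spec.encoder,
        head=spec.head,
        encoder_params=dict(spec.encoder_params),
        head_grid=dict(spec.head_grid),
        cv_folds=spec.cv_folds,
        random_state=seed,
    )
    return model.fit(train.values, train.labels)


def predict_hybrid(model: HybridClassifier, features: FeatureMatrix) -> np.ndarray:
    return model.predict(features.values)


@dataclass
class EnsembleVote:
    """Member predictions, one row per ensemble member."""

    member_predictions: np.ndarray  # (B members, n samples)
    task: str = "classification"

    def __post_init__(self) -> None:
        self.member_predictions = np.atleast_2d(
            np.asarray(self.member_predictions)
        )
        if self.member_predictions.shape[0] < 1:
            raise InputError("ensemble needs at least one member")
        if self.task not in ("classification", "regression"):
            raise InputError("task must be 'classification' or 'regression'")
        if self.task == "classification":
            vals = np.unique(self.member_predictions)
            if not np.isin(vals, (0, 1)).all():
                raise InputError("classification votes must be in {0, 1}")


def bagging_combine(votes: EnsembleVote) -> np.ndarray:
    """Aggregate member predictions.

    Classification: per-sample modal label; with an even member count a
    0-vs-1 tie resolves to 0 (lower label) deterministically. Regression:
    per-sample mean.
    """
    preds = votes.member_predictions
    if preds.size == 0:
        raise InputError("empty member predictions")
    if votes.task == "regression":
        return preds.mean(axis=0)
    b = preds.shape[0]
    ones = preds.sum(axis=0)
    # strict majority of 1s required; ties (ones == b/2) fall to label 0
    return (ones > b / 2).astype(np.int64)
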