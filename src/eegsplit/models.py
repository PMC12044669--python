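"""Classifier registry and the two deep encoders.

Classical classifiers (logistic regression, random forest, SVM, decision
tree, KNN, gradient boosting) are delegated to scikit-learn and tuned by
exhaustive grid search with stratified cross-validation; the small default
grids bracket the optima reported for this task (e.g. RF n_estimators 100,
KNN ``{n_neighbors: 7, weights: distance}``).

The deep encoders are scikit-learn-style transformers built on the NumPy
module library in :mod:`eegsplit.nn`:

* :class:`TransformerEncoder` — reshapes each epoch's ``channels x 6``
  statistical descriptors into one token per channel, embeds to ``d_model``,
  adds learned positional encodings over the channel index, applies
  ``n_layers`` multi-head self-attention blocks, and mean-pools to a latent
  vector. It is trained supervised through a temporary softmax head that is
  discarded after fitting.
* :class:`Autoencoder` — an MLP encoder/decoder trained to minimize the
  squared reconstruction error ``||x - x_hat||^2``; ``transform`` returns
  the latent code.

The module-level :func:`scaled_dot_attention` and
:func:`multi_head_attention` are standalone functional forms of the
attention primitive, independent of the trainable modules (the test suite
uses them as the oracle for the nn implementation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from . import nn
from .errors import ConfigError, InputError
from .preprocessing import FeatureMatrix

# ---------------------------------------------------------------------------
# Classical classifier registry
# ---------------------------------------------------------------------------

#: Default search grids. Each grid contains the best configuration reported
#: for this task (rf: n_estimators 100 / max_depth None; dtree: max_depth
#: 10; knn: n_neighbors 7, distance weights; svm: C 10, rbf; gboost:
#: learning_rate 0.2, n_estimators 100; logreg: C 0.1).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logreg": {"C": [0.1, 1.0, 10.0]},
    "rf": {"n_estimators": [50, 100], "max_depth": [None, 10]},
    "svm": {"C": [0.1, 1.0, 10.0], "kernel": ["rbf", "linear"]},
    "dtree": {"max_depth": [5, 10, None]},
    "knn": {"n_neighbors": [3, 5, 7], "weights": ["uniform", "distance"]},
    "gboost": {"learning_rate": [0.1, 0.2], "n_estimators": [50, 100]},
}


def make_classifier(name: str, random_state: int | None = 0, **params):
    """Instantiate a registered classical classifier."""
    if name == "logreg":
        return LogisticRegression(max_iter=2000, random_state=random_state, **params)
    if name == "rf":
        return RandomForestClassifier(random_state=random_state, **params)
    if name == "svm":
        return SVC(random_state=random_state, **params)
    if name == "dtree":
        return DecisionTreeClassifier(random_state=random_state, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "gboost":
        return GradientBoostingClassifier(random_state=random_state, **params)
    raise ConfigError(f"unknown classifier {name!r}; registered: {sorted(DEFAULT_GRIDS)}")


@dataclass
class ClassifierSpec:
    """A registered classifier name plus its hyperparameter search grid."""

    name: str
    grid: Mapping[str, list] = field(default_factory=dict)
    cv_folds: int = 4

    def __post_init__(self) -> None:
        if self.name not in DEFAULT_GRIDS:
            raise ConfigError(f"unknown classifier {self.name!r}")
        if not self.grid:
            self.grid = dict(DEFAULT_GRIDS[self.name])
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")


@dataclass
class FittedClassifier:
    """Grid-search outcome: winning configuration, CV accuracy, refit model."""

    spec: ClassifierSpec
    best_params: dict[str, Any]
    best_cv_score: float
    predictor: Any

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predictor.predict(X)


def _as_xy(features) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, FeatureMatrix):
        return features.values, features.labels
    raise InputError("expected a FeatureMatrix")


def grid_search_fit(
    spec: ClassifierSpec,
    features: FeatureMatrix | tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    standardize: bool = True,
) -> FittedClassifier:
    """Exhaustive grid search with stratified k-fold CV on accuracy.

    Features are z-scored inside each CV fold (fitted on the training part
    only) when ``standardize`` is on. Returns the best configuration, its
    mean CV accuracy, and a model refitted on all provided data.
    """
    if isinstance(features, FeatureMatrix):
        X, y = features.values, features.labels
    else:
        X, y = features
        y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("grid search needs both classes present")
    if counts.min() < spec.cv_folds:
        raise InputError(
            f"need at least cv_folds={spec.cv_folds} samples per class, "
            f"got minimum {counts.min()}"
        )
    from sklearn.pipeline import Pipeline

    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", make_classifier(spec.name, random_state=seed)))
    pipe = Pipeline(steps)
    grid = {f"clf__{k}": v for k, v in spec.grid.items()}
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, scoring="accuracy", cv=cv, refit=True)
    search.fit(X, y)
    best = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
    return FittedClassifier(
        spec=spec,
        best_params=best,
        best_cv_score=float(search.best_score_),
        predictor=search.best_estimator_,
    )


# ---------------------------------------------------------------------------
# Functional attention primitives
# ---------------------------------------------------------------------------


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, d_k: int | None = None
) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V.

    Each output row is a convex combination of V's rows; the weight matrix
    is row-stochastic by construction.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise InputError("Q and K must share their feature width")
    if K.shape[0] != V.shape[0]:
        raise InputError("K and V must share their row count")
    if d_k is None:
        d_k = K.shape[-1]
    scores = Q @ K.T / np.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=-1, keepdims=True)
    return weights @ V


def attention_weight_matrix(Q: np.ndarray, K: np.ndarray, d_k: int | None = None) -> np.ndarray:
    """The row-stochastic softmax(Q K^T / sqrt(d_k)) weight matrix."""
    Q, K = np.asarray(Q, float), np.asarray(K, float)
    if d_k is None:
        d_k = K.shape[-1]
    scores = Q @ K.T / np.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    return w / w.sum(axis=-1, keepdims=True)


def multi_head_attention(
    X: np.ndarray,
    head_projections: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    W_O: np.ndarray,
) -> np.ndarray:
    """Concatenate per-head scaled dot-product attention, project by W_O.

    ``head_projections`` is a sequence of ``(W_Q, W_K, W_V)`` triples, one
    per head; self-attention is applied (queries, keys and values all come
    from ``X``).
    """
    X = np.asarray(X, dtype=np.float64)
    outs = []
    for W_Q, W_K, W_V in head_projections:
        q, k, v = X @ W_Q, X @ W_K, X @ W_V
        outs.append(scaled_dot_attention(q, k, v, d_k=k.shape[-1]))
    concat = np.concatenate(outs, axis=-1)
    if concat.shape[-1] != W_O.shape[0]:
        raise ConfigError(
            f"concatenated head width {concat.shape[-1]} does not match "
            f"W_O rows {W_O.shape[0]}"
        )
    return concat @ W_O


# ---------------------------------------------------------------------------
# Deep encoders (scikit-learn estimator API)
# ---------------------------------------------------------------------------


@dataclass
class LatentRepresentation:
    """Per-epoch encoder outputs exchanged with downstream heads."""

    z: np.ndarray
    producer: str

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if not np.all(np.isfinite(self.z)):
            raise InputError("latent representation contains non-finite entries")


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start : start + batch_size]


class TransformerEncoder(BaseEstimator, TransformerMixin):
    """Channel-token transformer encoder for epoch feature vectors.

    Each ``n_channels * 6`` feature row becomes ``n_channels`` tokens of 6
    descriptors. Fitting trains the backbone plus a temporary softmax
    classification head by minibatch Adam on cross-entropy; ``transform``
    returns the mean-pooled ``d_model``-wide latents from the frozen
    backbone.

    Parameters
    ----------
    d_model : embedding width (latent width equals it).
    n_heads : attention heads; must divide ``d_model``.
    n_layers : encoder blocks.
    d_ff : feed-forward hidden width.
    n_epochs, lr, batch_size : Adam training schedule.
    standardize : z-score features before tokenization (fitted on train).
    random_state : seed for init and batch order.
    """

    def __init__(
        self,
        token_dim: int = 6,
        d_model: int = 32,
        n_heads: int = 4,
        n_layers: int = 2,
        d_ff: int = 64,
        n_epochs: int = 30,
        lr: float = 1e-3,
        batch_size: int = 64,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.token_dim = token_dim
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.n_epochs = n_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.standardize = standardize
        self.random_state = random_state

    # -- internal ----------------------------------------------------------
    def _tokenize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] % self.token_dim != 0:
            raise InputError(
                f"feature width {X.shape[1] if X.ndim == 2 else '?'} is not a "
                f"multiple of token_dim={self.token_dim}"
            )
        n_tokens = X.shape[1] // self.token_dim
        return X.reshape(X.shape[0], n_tokens, self.token_dim), n_tokens

    def fit(self, X, y):
        if self.d_model % self.n_heads != 0:
            raise ConfigError("d_model must be divisible by n_heads")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise InputError("transformer training needs at least two classes")
        self.classes_ = classes
        y_idx = np.searchsorted(classes, y)

        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        tokens, n_tokens = self._tokenize(Xs)
        self.n_tokens_ = n_tokens
        self.n_features_in_ = X.shape[1]

        rng = np.random.default_rng(self.random_state)
        self.backbone_ = nn.TransformerBackbone(
            n_tokens, self.token_dim, self.d_model, self.n_heads,
            self.n_layers, self.d_ff, rng,
        )
        head = nn.Linear(self.d_model, len(classes), rng)
        params = self.backbone_.parameters() + head.parameters()
        opt = nn.Adam(params, lr=self.lr)
        losses = []
        for _ in range(self.n_epochs):
            epoch_loss, n_seen = 0.0, 0
            for batch in _batches(len(tokens), self.batch_size, rng):
                opt.zero_grad()
                z = self.backbone_.forward(tokens[batch])
                logits = head.forward(z)
                loss, dlogits = nn.softmax_cross_entropy(logits, y_idx[batch])
                self.backbone_.backward(head.backward(dlogits))
                opt.step()
                epoch_loss += loss * len(batch)
                n_seen += len(batch)
            losses.append(epoch_loss / max(n_seen, 1))
        self.loss_curve_ = losses
        # the softmax head is kept only for optional probability readout
        self._head = head
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "backbone_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        tokens, _ = self._tokenize(Xs)
        return self.backbone_.forward(tokens)

    def encode(self, features: FeatureMatrix) -> LatentRepresentation:
        return LatentRepresentation(self.transform(features.values), "transformer")


class Autoencoder(BaseEstimator, TransformerMixin):
    """MLP autoencoder minimizing the squared reconstruction error.

    ``transform`` returns the latent code z = f_enc(x);
    ``inverse_transform`` the reconstruction x_hat = f_dec(z). With
    ``activation='linear'`` the model is a linear autoencoder whose optimal
    reconstruction error equals the best rank-``latent_dim`` error.
    """

    def __init__(
        self,
        latent_dim: int = 16,
        hidden: tuple[int, ...] = (64,),
        activation: str = "relu",
        n_epochs: int = 100,
        lr: float = 1e-3,
        batch_size: int = 64,
        standardize: bool = False,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.activation = activation
        self.n_epochs = n_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        d_in = X.shape[1]
        if self.latent_dim >= d_in:
            raise ConfigError(
                f"latent_dim={self.latent_dim} must be smaller than the "
                f"input width {d_in}"
            )
        if self.activation not in ("relu", "linear"):
            raise ConfigError("activation must be 'relu' or 'linear'")
        act = nn.ReLU if self.activation == "relu" else None

        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X

        rng = np.random.default_rng(self.random_state)
        enc_sizes = [d_in, *self.hidden, self.latent_dim]
        dec_sizes = [self.latent_dim, *reversed(self.hidden), d_in]
        self.encoder_ = nn.mlp(enc_sizes, rng, hidden_activation=act)
        self.decoder_ = nn.mlp(dec_sizes, rng, hidden_activation=act)
        params = self.encoder_.parameters() + self.decoder_.parameters()
        opt = nn.Adam(params, lr=self.lr)
        losses = []
        for _ in range(self.n_epochs):
            epoch_loss, n_seen = 0.0, 0
            for batch in _batches(len(Xs), self.batch_size, rng):
                opt.zero_grad()
                z = self.encoder_.forward(Xs[batch])
                xhat = self.decoder_.forward(z)
                loss, dxhat = nn.squared_error(Xs[batch], xhat)
                self.encoder_.backward(self.decoder_.backward(dxhat))
                opt.step()
                epoch_loss += loss * len(batch)
                n_seen += len(batch)
            losses.append(epoch_loss / max(n_seen, 1))
        self.loss_curve_ = losses
        self.n_features_in_ = d_in
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "encoder_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        return self.encoder_.forward(Xs)

    def inverse_transform(self, Z) -> np.ndarray:
        check_is_fitted(self, "decoder_")
        xhat = self.decoder_.forward(np.asarray(Z, dtype=np.float64))
        if self.scaler_ is not None:
            xhat = self.scaler_.inverse_transform(xhat)
        return xhat

    def reconstruction_error(self, X) -> float:
        """Mean per-sample squared reconstruction norm on X."""
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else np.asarray(X, float)
        xhat = self.decoder_.forward(self.encoder_.forward(Xs))
        return float(np.sum((Xs - xhat) ** 2) / len(Xs))

    def encode(self, features: FeatureMatrix) -> LatentRepresentation:
        return LatentRepresentation(self.transform(features.values), "autoencoder")


def autoencoder_fit(features: FeatureMatrix, config: Autoencoder | None = None, **kwargs) -> Autoencoder:
    """Functional wrapper: fit an :class:`Autoencoder` on a FeatureMatrix."""
    model = config if config is not None else Autoencoder(**kwargs)
    return model.fit(features.values)


def autoencoder_encode(features: FeatureMatrix, fitted: Autoencoder) -> LatentRepresentation:
    return fitted.encode(features)


def transformer_encode(features: FeatureMatrix, fitted: TransformerEncoder) -> LatentRepresentation:
    return fitted.encode(features)
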