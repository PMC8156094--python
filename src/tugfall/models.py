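"""The fall-risk classifiers: a 1-D CNN on raw signal windows and an SVM
on summary statistics.

The CNN is the screening model at the core of the package: four
Conv-BN-ReLU blocks with max pooling after the second and fourth blocks,
a flatten, and a single fully connected unit with sigmoid output giving
P(faller).  A 0.5 threshold (ties to the faller class — screening favours
sensitivity) converts the probability to a binary call.

Both classifiers follow the scikit-learn estimator protocol (``fit`` /
``predict`` / ``predict_proba`` / ``get_params``); fitted attributes carry
a trailing underscore.  The faller class is encoded as 1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import _nn
from ._nn import Adam, BatchNorm1d, Conv1d, Dense, Flatten, MaxPool1d, ReLU


@dataclass
class CnnConfig:
    """Architecture and training hyperparameters of the 1-D CNN.

    The block layout (4 conv blocks, pooling after blocks 2 and 4, single
    sigmoid output) is fixed; filter counts, kernel size, pool size and the
    optimization settings are free.
    """

    filters: tuple[int, int, int, int] = (32, 32, 64, 64)
    kernel_size: int = 5
    pool_size: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if len(self.filters) != 4 or any(f < 1 for f in self.filters):
            raise ValueError("filters must be 4 positive integers")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.pool_size < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("pool/epochs/batch sizes must be positive")


class CnnFallClassifier(BaseEstimator, ClassifierMixin):
    """1-D convolutional fall-risk classifier on (n, window, channels) input.

    Layer sequence: [Conv, BN, ReLU] x2, MaxPool, [Conv, BN, ReLU] x2,
    MaxPool, Flatten, FC(1), sigmoid.  Trained with Adam on binary
    cross-entropy; deterministic given ``random_state``.

    Parameters mirror :class:`CnnConfig`; ``predict_fall_probability``
    returns P(faller) per segment and ``predict`` thresholds it at
    ``threshold`` with ties assigned to the faller class.
    """

    def __init__(self, filters=(32, 32, 64, 64), kernel_size=5, pool_size=2,
                 learning_rate=1e-3, batch_size=64, epochs=30,
                 threshold=0.5, random_state=0, verbose=0):
        self.filters = filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.threshold = threshold
        self.random_state = random_state
        self.verbose = verbose

    # -- construction -----------------------------------------------------
    def _build(self, n_channels: int, length: int,
               rng: np.random.Generator) -> None:
        f = tuple(self.filters)
        if length < self.kernel_size:
            raise ValueError("input window shorter than the receptive field")
        layers = [
            Conv1d(n_channels, f[0], self.kernel_size, rng),
            BatchNorm1d(f[0]), ReLU(),
            Conv1d(f[0], f[1], self.kernel_size, rng),
            BatchNorm1d(f[1]), ReLU(),
            MaxPool1d(self.pool_size),
            Conv1d(f[1], f[2], self.kernel_size, rng),
            BatchNorm1d(f[2]), ReLU(),
            Conv1d(f[2], f[3], self.kernel_size, rng),
            BatchNorm1d(f[3]), ReLU(),
            MaxPool1d(self.pool_size),
            Flatten(),
        ]
        out_len = (length // self.pool_size) // self.pool_size
        if out_len < 1:
            raise ValueError("input window too short for two pooling stages")
        layers.append(Dense(f[3] * out_len, 1, rng))
        self.layers_ = layers
        self.n_parameters_ = sum(lay.n_parameters for lay in layers)

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers_:
            x = layer.forward(x, train)
        return _nn.sigmoid(x[:, 0])

    def _backward(self, dz: np.ndarray) -> None:
        d = dz[:, None]
        for layer in reversed(self.layers_):
            d = layer.backward(d)

    @staticmethod
    def _validate_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                "X must be 3-D (n_segments, window_samples, n_channels)")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set contains a single class")
        if not set(classes) <= {0.0, 1.0}:
            raise ValueError("labels must be 0/1")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1] * X.shape[2]
        self.input_shape_ = X.shape[1:]
        rng = np.random.default_rng(self.random_state)
        xt = np.ascontiguousarray(X.transpose(0, 2, 1))  # (n, C, L)
        self._build(xt.shape[1], xt.shape[2], rng)
        opt = Adam(self.layers_, lr=self.learning_rate)
        n = len(xt)
        losses = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = xt[idx], y[idx]
                p = self._forward(xb, train=True)
                loss = _nn.bce_loss(p, yb)
                self._backward((p - yb) / len(yb))
                opt.step()
                epoch_loss += loss * len(yb)
                seen += len(yb)
            losses.append(epoch_loss / seen)
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs} "
                      f"loss={losses[-1]:.4f}")
        self.loss_curve_ = np.array(losses)
        return self

    def predict_fall_probability(self, X) -> np.ndarray:
        """P(faller) for each segment, in [0, 1]."""
        if not hasattr(self, "layers_"):
            raise ValueError("classifier is not fitted")
        X = self._validate_X(X)
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"segment shape {X.shape[1:]} does not match the fitted "
                f"input shape {self.input_shape_}")
        xt = np.ascontiguousarray(X.transpose(0, 2, 1))
        out = [self._forward(xt[i:i + 256], train=False)
               for i in range(0, len(xt), 256)]
        return np.concatenate(out) if out else np.zeros(0)

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_fall_probability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return classify(self.predict_fall_probability(X), self.threshold)


class SvmFallClassifier(BaseEstimator, ClassifierMixin):
    """RBF support vector machine on the nine per-subject summary statistics.

    Features are standardized inside the estimator.  ``predict_fall_
    probability`` passes the signed margin through a logistic so the score
    lives on [0, 1] and supports ROC/AUC analysis; ``predict`` thresholds
    at 0.5 (equivalently, at zero margin), ties to the faller class.
    """

    def __init__(self, kernel="rbf", C=1.0, gamma="scale", threshold=0.5,
                 random_state=0):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_subjects, n_features)")
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                random_state=self.random_state))
        self.pipeline_.fit(X, y)
        return self

    def decision_function(self, X) -> np.ndarray:
        return self.pipeline_.decision_function(np.asarray(X, dtype=float))

    def predict_fall_probability(self, X) -> np.ndarray:
        return _nn.sigmoid(self.decision_function(X))

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_fall_probability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return classify(self.predict_fall_probability(X), self.threshold)


# -- thin functional wrappers over the estimators --------------------------

def build_cnn(config: CnnConfig | None = None, **overrides
              ) -> CnnFallClassifier:
    """Untrained CNN classifier from a :class:`CnnConfig`."""
    config = config or CnnConfig()
    return CnnFallClassifier(
        filters=config.filters, kernel_size=config.kernel_size,
        pool_size=config.pool_size, learning_rate=config.learning_rate,
        batch_size=config.batch_size, epochs=config.epochs,
        random_state=config.seed, **overrides)


def train_classifier(model, X, y):
    """Fit a (cloned) classifier on training segments or features."""
    fitted = clone(model)
    fitted.fit(X, y)
    return fitted


def predict_fall_probability(model, X) -> np.ndarray:
    return model.predict_fall_probability(X)


def classify(p_fall: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary call from P(faller): faller iff p >= threshold."""
    p = np.asarray(p_fall, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(int)


def fit_svm(features, labels, **kw) -> SvmFallClassifier:
    """Fit the SVM baseline on (n_subjects, 9) summary features."""
    return SvmFallClassifier(**kw).fit(features, labels)
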