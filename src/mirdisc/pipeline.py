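"""End-to-end prediction estimator: CNN encoder codes + Gaussian NB.

The softmax head trains the encoder; prediction replaces it with a
Gaussian Naive Bayes classifier fit on the 256-d intermediate codes,
which works better than the head itself in the small-positive-sample
regime this task lives in.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .classifier import CodeGaussianNB
from .encoder import CNNEncoder


class CnnGnbClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier: fused embedding row -> CNN code -> GaussianNB posterior.

    Parameters mirror :class:`CNNEncoder`; ``classifier`` is any estimator
    with fit/predict_proba over the codes (default :class:`CodeGaussianNB`).
    Class index 1 is the disease-associated (positive) class, and
    :meth:`predict` thresholds its posterior at 0.5.
    """

    def __init__(
        self,
        variant: str = "full",
        epochs: int = 100,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        patience: int = 10,
        dropout: float = 0.5,
        code_dim: int = 256,
        conv_channels: int = 16,
        standardize: bool = False,
        classifier: BaseEstimator | None = None,
        random_state: int = 0,
    ):
        self.variant = variant
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.dropout = dropout
        self.code_dim = code_dim
        self.conv_channels = conv_channels
        self.standardize = standardize
        self.classifier = classifier
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray):
        self.encoder_ = CNNEncoder(
            variant=self.variant,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            patience=self.patience,
            dropout=self.dropout,
            code_dim=self.code_dim,
            conv_channels=self.conv_channels,
            standardize=self.standardize,
            random_state=self.random_state,
        ).fit(X, y)
        codes = self.encoder_.transform(X)
        base = self.classifier if self.classifier is not None else CodeGaussianNB()
        self.classifier_ = clone(base).fit(codes, np.asarray(y).astype(int))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict_proba(self.encoder_.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
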