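"""Gaussian Naive Bayes over encoder codes — the final prediction stage.

The model assumes per-class feature independence with Gaussian
likelihoods: priors are class frequencies, per-class means/variances are
sample moments, and every variance receives the standard smoothing term
``1e-9 * max feature variance`` so constant features cannot produce a
zero denominator. Posteriors are evaluated in log space (log-sum-exp),
so extreme densities never overflow.

Fitting is delegated to :class:`sklearn.naive_bayes.GaussianNB` with its
default parameters; the fitted moments are stored in a small portable
:class:`GaussianNBModel` and posteriors are recomputed from them here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.naive_bayes import GaussianNB
from sklearn.utils.validation import check_is_fitted


@dataclass
class GaussianNBModel:
    """Fitted priors and per-class Gaussian moments (2 classes x d features)."""

    class_priors: np.ndarray
    means: np.ndarray
    variances: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.class_priors = np.asarray(self.class_priors, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if abs(self.class_priors.sum() - 1.0) > 1e-12 or np.any(self.class_priors <= 0):
            raise ValueError("class priors must be positive and sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive after smoothing")

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def save(self, path: str | Path) -> None:
        payload = {
            "class_priors": self.class_priors.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GaussianNBModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            class_priors=np.array(payload["class_priors"]),
            means=np.array(payload["means"]),
            variances=np.array(payload["variances"]),
        )


def fit_gaussian_nb(codes: np.ndarray, labels: np.ndarray) -> GaussianNBModel:
    """Fit priors and smoothed per-class moments (default smoothing 1e-9)."""
    codes = np.asarray(codes, dtype=float)
    labels = np.asarray(labels).astype(int).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to fit the classifier")
    nb = GaussianNB().fit(codes, labels)
    return GaussianNBModel(
        class_priors=nb.class_prior_, means=nb.theta_, variances=nb.var_
    )


def predict_proba(model: GaussianNBModel, codes: np.ndarray) -> np.ndarray:
    """Per-row class posteriors, computed in log space.

    posterior(c | x) proportional to prior(c) * prod_j N(x_j; mu_cj, var_cj),
    normalized by log-sum-exp so rows sum to 1 and stay finite for any
    finite input.
    """
    codes = np.atleast_2d(np.asarray(codes, dtype=float))
    if codes.shape[1] != model.n_features:
        raise ValueError(
            f"code width {codes.shape[1]} does not match model width {model.n_features}"
        )
    log_joint = np.empty((codes.shape[0], len(model.class_priors)))
    for c in range(len(model.class_priors)):
        var = model.variances[c]
        ll = -0.5 * (
            np.log(2.0 * np.pi * var) + (codes - model.means[c]) ** 2 / var
        ).sum(axis=1)
        log_joint[:, c] = np.log(model.class_priors[c]) + ll
    return np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))


class CodeGaussianNB(BaseEstimator, ClassifierMixin):
    """Estimator facade over :func:`fit_gaussian_nb` / :func:`predict_proba`.

    Any classifier exposing this fit/predict_proba surface can replace it
    in the pipeline (the stage is pluggable); only GaussianNB ships.
    """

    def fit(self, X: np.ndarray, y: np.ndarray):
        self.model_ = fit_gaussian_nb(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return predict_proba(self.model_, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
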