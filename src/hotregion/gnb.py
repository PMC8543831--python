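"""From-scratch Gaussian naive Bayes hot-spot classifier.

Class priors are the training class frequencies; each feature gets a
per-class univariate normal N(mu, sigma^2) fitted by sample mean and standard
deviation, with sigma floored at ``sigma_floor_scale`` times the largest
feature range to survive zero-variance columns. Classification evaluates the
posterior odds ratio

    f(E) = [p(C=1)/p(C=0)] * prod_i p(x_i | C=1) / p(x_i | C=0)

in log space (so ~80 features cannot underflow) and assigns the hot class
when the ratio is >= 1, the boundary going to the hot class.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .features import FeatureTable

DEFAULT_SIGMA_FLOOR_SCALE = 1e-9


@runtime_checkable
class Classifier(Protocol):
    """Uniform fit/predict contract so alternative models can plug in.

    ``predict`` is defined only after ``fit``; labels are 0 (non-hot) and
    1 (hot). ``uses_feature_selection`` marks whether the model should
    participate in the feature-selection stage (neural networks that fuse
    features internally typically opt out).
    """

    name: str
    hyperparameters: dict
    uses_feature_selection: bool

    def fit(self, table: FeatureTable) -> "Classifier": ...

    def predict(self, rows: np.ndarray) -> np.ndarray: ...


@dataclass
class GNBModel:
    """Fitted parameters: priors and per-class, per-feature (mu, sigma)."""

    feature_names: list[str]
    prior: np.ndarray  # shape (2,), sums to 1
    mu: np.ndarray  # shape (2, p)
    sigma: np.ndarray  # shape (2, p), all > 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "prior": self.prior.tolist(),
                "mu": self.mu.tolist(),
                "sigma": self.sigma.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GNBModel":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            prior=np.array(d["prior"]),
            mu=np.array(d["mu"]),
            sigma=np.array(d["sigma"]),
        )


def fit_gnb(
    table: FeatureTable, sigma_floor_scale: float = DEFAULT_SIGMA_FLOOR_SCALE
) -> GNBModel:
    """Fit priors and per-class Gaussians; both classes must be present."""
    x = table.x.to_numpy(dtype=float)
    y = table.labels
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"training data must contain both classes, got {classes}")
    n, p = x.shape
    ranges = x.max(axis=0) - x.min(axis=0)
    floor = sigma_floor_scale * max(float(ranges.max()), 1.0)
    prior = np.array([np.mean(y == 0), np.mean(y == 1)])
    mu = np.vstack([x[y == c].mean(axis=0) for c in (0, 1)])
    sigma = np.vstack([x[y == c].std(axis=0, ddof=0) for c in (0, 1)])
    if (sigma < floor).any():
        warnings.warn("zero-variance feature in a class; sigma floored", stacklevel=2)
    sigma = np.maximum(sigma, floor)
    return GNBModel(list(table.feature_names), prior, mu, sigma)


def gaussian_density(x: float, mu: float, sigma: float) -> float:
    """Univariate normal density N(x; mu, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (x - mu) / sigma
    return math.exp(-0.5 * z * z) / (sigma * math.sqrt(2 * math.pi))


def _log_likelihood(model: GNBModel, rows: np.ndarray) -> np.ndarray:
    """log p(row | class) + log prior, shape (n, 2)."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != model.mu.shape[1]:
        raise ValueError(
            f"row dimension {rows.shape[1]} does not match model "
            f"dimension {model.mu.shape[1]}"
        )
    out = np.empty((rows.shape[0], 2))
    for c in (0, 1):
        z = (rows - model.mu[c]) / model.sigma[c]
        out[:, c] = (
            math.log(model.prior[c])
            - np.sum(np.log(model.sigma[c]))
            - 0.5 * rows.shape[1] * math.log(2 * math.pi)
            - 0.5 * np.sum(z * z, axis=1)
        )
    return out


def posterior_ratio(model: GNBModel, row: np.ndarray) -> float:
    """Posterior odds p(C=1|E)/p(C=0|E), accumulated in log space."""
    ll = _log_likelihood(model, row)
    return float(np.exp(ll[0, 1] - ll[0, 0]))


def predict_gnb(model: GNBModel, rows: np.ndarray) -> np.ndarray:
    """Label 1 (hot) iff the posterior odds ratio is >= 1."""
    ll = _log_likelihood(model, rows)
    return (ll[:, 1] >= ll[:, 0]).astype(int)


@dataclass
class GaussianNaiveBayes:
    """Classifier-interface wrapper around :func:`fit_gnb`/:func:`predict_gnb`."""

    sigma_floor_scale: float = DEFAULT_SIGMA_FLOOR_SCALE
    name: str = "gnb"
    uses_feature_selection: bool = True
    hyperparameters: dict = field(default_factory=dict)
    model_: GNBModel | None = None

    def fit(self, table: FeatureTable) -> "GaussianNaiveBayes":
        self.model_ = fit_gnb(table, self.sigma_floor_scale)
        return self

    def predict(self, rows: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("predict called before fit")
        return predict_gnb(self.model_, rows)


class SklearnAdapter:
    """Wrap any scikit-learn style estimator behind the classifier contract.

    Lets externally implemented models (support vector machines, boosted
    trees, random forests, neural networks) participate in incremental
    feature selection and evaluation without being reimplemented here.
    """

    def __init__(self, estimator, name: str, uses_feature_selection: bool = True):
        self.estimator = estimator
        self.name = name
        self.uses_feature_selection = uses_feature_selection
        self.hyperparameters = getattr(estimator, "get_params", dict)()

    def fit(self, table: FeatureTable) -> "SklearnAdapter":
        self.estimator.fit(table.x.to_numpy(dtype=float), table.labels)
        return self

    def predict(self, rows: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.atleast_2d(rows))).astype(int)
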