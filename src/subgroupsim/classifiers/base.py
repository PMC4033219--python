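"""Shared fit/predict contract and per-method configuration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


class FitError(ValueError):
    """Raised when a training set violates a method's preconditions."""


@dataclass
class LDAConfig:
    #: "data" estimates priors as training class frequencies (the
    #: recommended practice); "uniform" uses equal priors.
    priors: str = "data"


@dataclass
class LRConfig:
    tol: float = 1e-8
    max_iter: int = 50


@dataclass
class CARTConfig:
    #: a split must reduce deviance by at least this fraction of the
    #: root-node deviance
    min_deviance_fraction: float = 0.01
    #: both children of a split must contain at least this many rows
    min_node_size: int = 10


@dataclass
class GAMConfig:
    #: relative deviance-change threshold for the fitting iterations
    epsilon: float = 7e-7
    max_iterations: int = 30
    #: target degrees of freedom of each predictor's cubic spline
    spline_df: int = 4
    #: how three or more classes are handled by the binary-logit smoother:
    #: "ovr" fits one-vs-rest models and renormalizes the class scores;
    #: "ordinal" fits a single model to the class index mapped onto [0, 1]
    #: and classifies to the nearest class grid point.
    multiclass: str = "ordinal"


@dataclass
class MIXDAConfig:
    em_tolerance: float = 5e-5
    em_max_iterations: int = 100
    subclasses_per_class: int = 2


@dataclass
class MethodConfig:
    """Hyperparameters of all five methods, with the study defaults."""

    lda: LDAConfig = field(default_factory=LDAConfig)
    lr: LRConfig = field(default_factory=LRConfig)
    cart: CARTConfig = field(default_factory=CARTConfig)
    gam: GAMConfig = field(default_factory=GAMConfig)
    mixda: MIXDAConfig = field(default_factory=MIXDAConfig)

    def __post_init__(self) -> None:
        if self.lr.tol <= 0 or self.gam.epsilon <= 0 or self.mixda.em_tolerance <= 0:
            raise ValueError("all convergence tolerances must be positive")
        if min(self.lr.max_iter, self.gam.max_iterations, self.mixda.em_max_iterations) < 1:
            raise ValueError("iteration caps must be at least 1")
        if self.mixda.subclasses_per_class < 1:
            raise ValueError("subclasses_per_class must be at least 1")

    @classmethod
    def from_dict(cls, d: dict) -> "MethodConfig":
        """Build from a nested mapping keyed by method name."""
        kwargs = {}
        for name, sub_cls in (
            ("lda", LDAConfig),
            ("lr", LRConfig),
            ("cart", CARTConfig),
            ("gam", GAMConfig),
            ("mixda", MIXDAConfig),
        ):
            if name in d:
                kwargs[name] = sub_cls(**d[name])
        return cls(**kwargs)


class ClassifierModel:
    """Base class: a fitted model mapping rows to per-class posteriors.

    Subclasses implement :meth:`predict_proba`; prediction is the argmax
    of the posterior with ties broken to the lowest class index.
    """

    method: str = "base"

    def __init__(self, classes: np.ndarray, n_features: int):
        self.classes_ = np.asarray(classes)
        self.n_features_ = int(n_features)

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"X must have {self.n_features_} columns, got shape {X.shape}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def predict(model: ClassifierModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Uniform prediction contract: ``(labels, posteriors)``.

    Labels are the argmax of each posterior row, ties to the lowest class
    index; shapes are ``(n,)`` and ``(n, K)``.  An empty ``X`` yields
    empty outputs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features_:
        raise ValueError(
            f"X must have {model.n_features_} columns, got shape {X.shape}"
        )
    if X.shape[0] == 0:
        return model.classes_[:0].copy(), np.empty((0, len(model.classes_)))
    proba = model.predict_proba(X)
    return model.classes_[np.argmax(proba, axis=1)], proba


def class_index(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique classes and the index of each row's class."""
    classes, idx = np.unique(np.asarray(y), return_inverse=True)
    if len(classes) < 2:
        raise FitError("training data must contain at least 2 classes")
    return classes, idx


def pooled_ml_covariance(X: np.ndarray, idx: np.ndarray, K: int) -> np.ndarray:
    """Pooled within-class covariance, maximum-likelihood denominator ``n``."""
    n, p = X.shape
    S = np.zeros((p, p))
    for k in range(K):
        Xk = X[idx == k]
        if len(Xk) == 0:
            continue
        d = Xk - Xk.mean(axis=0)
        S += d.T @ d
    return S / n


def safe_cho_factor(S: np.ndarray, context: str):
    """Cholesky factor of ``S``, ridge-regularized if singular.

    Adds ``1e-8 * mean(diag)`` to the diagonal on failure and warns.
    """
    scale = float(np.mean(np.diag(S)))
    singular = np.linalg.eigvalsh(S)[0] <= 1e-10 * max(scale, 1e-300)
    if not singular:
        try:
            return linalg.cho_factor(S, lower=True)
        except linalg.LinAlgError:
            singular = True
    eps = 1e-8 * scale if scale > 0 else 1e-8
    warnings.warn(
        f"{context}: singular covariance, adding ridge {eps:.2e} to the diagonal",
        stacklevel=2,
    )
    return linalg.cho_factor(S + eps * np.eye(S.shape[0]), lower=True)


def gaussian_logpdf(X: np.ndarray, mean: np.ndarray, cho) -> np.ndarray:
    """Multivariate-normal log density with a pre-factored covariance."""
    p = X.shape[1]
    d = X - mean
    z = linalg.cho_solve(cho, d.T)
    maha = np.einsum("ij,ji->i", d, z)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return -0.5 * (maha + logdet + p * np.log(2.0 * np.pi))
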