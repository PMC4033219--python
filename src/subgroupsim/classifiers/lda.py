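"""Linear discriminant analysis with data-estimated priors.

Classic Gaussian discriminant rule: one mean per class, one covariance
pooled across classes (maximum-likelihood denominator ``n``, so that a
one-subclass mixture discriminant model reduces to exactly this rule),
posterior proportional to ``prior_k * phi(x; mu_k, Sigma)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .base import (
    ClassifierModel,
    MethodConfig,
    class_index,
    gaussian_logpdf,
    pooled_ml_covariance,
    safe_cho_factor,
)


class LDAModel(ClassifierModel):
    method = "lda"

    def __init__(self, classes, means, covariance, priors):
        super().__init__(classes, means.shape[1])
        self.means_ = means
        self.covariance_ = covariance
        self.priors_ = priors
        self._cho = safe_cho_factor(covariance, "LDA")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        log_post = np.column_stack(
            [
                np.log(self.priors_[k]) + gaussian_logpdf(X, self.means_[k], self._cho)
                for k in range(len(self.classes_))
            ]
        )
        return np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))


def fit_lda(train, config: MethodConfig | None = None) -> LDAModel:
    """Fit LDA on a labeled training set.

    Priors are the training class frequencies unless the configuration
    asks for uniform priors.
    """
    config = config or MethodConfig()
    X = np.asarray(train.X, dtype=float)
    classes, idx = class_index(train.y_group)
    K = len(classes)
    means = np.vstack([X[idx == k].mean(axis=0) for k in range(K)])
    cov = pooled_ml_covariance(X, idx, K)
    if config.lda.priors == "uniform":
        priors = np.full(K, 1.0 / K)
    else:
        priors = np.bincount(idx, minlength=K) / len(idx)
    return LDAModel(classes, means, cov, priors)
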