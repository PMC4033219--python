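"""Baseline-category multinomial logistic regression by Newton-Raphson.

The last class (highest label) is the reference category; each other
class has its own coefficient vector on ``[1, x]``.  With two classes
this is ordinary binary logistic regression.  Maximization uses full
Newton steps with backtracking; under complete or quasi-separation the
likelihood has no maximizer, so fitting stops at the iteration cap with a
warning and the saturated posteriors are still usable for prediction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp

from .base import ClassifierModel, MethodConfig, class_index


class MultinomialLRModel(ClassifierModel):
    method = "lr"

    def __init__(self, classes, coef, converged):
        # coef: (K-1, p+1), reference = last class
        super().__init__(classes, coef.shape[1] - 1)
        self.coef_ = coef
        self.converged_ = converged

    def _logits(self, X: np.ndarray) -> np.ndarray:
        Z = np.column_stack([np.ones(len(X)), X])
        eta = Z @ self.coef_.T
        return np.column_stack([eta, np.zeros(len(X))])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        eta = self._logits(X)
        return np.exp(eta - logsumexp(eta, axis=1, keepdims=True))


def _loglik(eta: np.ndarray, yidx: np.ndarray) -> float:
    lse = logsumexp(eta, axis=1)
    return float(np.sum(eta[np.arange(len(yidx)), yidx] - lse))


def fit_multinomial_lr(train, config: MethodConfig | None = None) -> MultinomialLRModel:
    """Fit by Newton iterations on the multinomial log-likelihood."""
    config = config or MethodConfig()
    tol, max_iter = config.lr.tol, config.lr.max_iter
    X = np.asarray(train.X, dtype=float)
    classes, yidx = class_index(train.y_group)
    K = len(classes)
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    q = p + 1
    beta = np.zeros((K - 1) * q)
    Y = np.zeros((n, K - 1))
    Y[np.arange(n), np.minimum(yidx, K - 2)] = (yidx < K - 1).astype(float)

    def eta_of(b):
        return np.column_stack([Z @ b.reshape(K - 1, q).T, np.zeros(n)])

    ll = _loglik(eta_of(beta), yidx)
    converged = False
    for _ in range(max_iter):
        eta = eta_of(beta)
        P = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))[:, : K - 1]
        grad = (Z.T @ (Y - P)).T.reshape(-1)  # ordered by class blocks
        # block Hessian of the negative log-likelihood
        H = np.empty(((K - 1) * q, (K - 1) * q))
        for a in range(K - 1):
            for b in range(a, K - 1):
                w = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
                Hab = Z.T @ (Z * (-w)[:, None])
                H[a * q : (a + 1) * q, b * q : (b + 1) * q] = Hab
                if b != a:
                    H[b * q : (b + 1) * q, a * q : (a + 1) * q] = Hab.T
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.trace(-H) / len(grad)
            step = np.linalg.solve(-H + ridge * np.eye(len(grad)), grad)
        # backtracking line search on the log-likelihood
        t, new_ll = 1.0, -np.inf
        for _half in range(30):
            cand = beta + t * step
            new_ll = _loglik(eta_of(cand), yidx)
            if np.isfinite(new_ll) and new_ll >= ll:
                break
            t *= 0.5
        if not np.isfinite(new_ll) or new_ll < ll:
            break
        beta = beta + t * step
        if new_ll - ll <= tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    saturated = bool(np.max(np.abs(eta_of(beta))) > 30)
    if not converged or saturated:
        warnings.warn(
            "multinomial logistic regression "
            + ("did not converge" if not converged else "saturated")
            + " (possible complete or quasi-separation); returning current fit",
            stacklevel=2,
        )
    return MultinomialLRModel(classes, beta.reshape(K - 1, q), converged and not saturated)
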