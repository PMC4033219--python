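"""Mixture discriminant analysis: Gaussian subclasses per known class.

Each known class ``k`` is modeled as a mixture of ``R`` Gaussian
subclasses sharing a single covariance matrix across all subclasses of
all classes:

    p(x | class k) = sum_r pi_kr * phi(x; mu_kr, Sigma),  sum_r pi_kr = 1.

Parameters are estimated by EM over the within-class subclass
responsibilities (class labels are observed, subclass labels are
latent); the observed-data log-likelihood is non-decreasing across
iterations, and fitting stops when its relative change falls below the
EM tolerance or at the iteration cap.  Class posteriors combine the
class mixture densities with data-estimated class priors; the fitted
model also exposes per-observation subclass responsibilities, the
latent-subgroup readout that distinguishes this method from the others
in the benchmark.

Initialization is deterministic: within each class, subclass centers are
seeded by a farthest-point traversal (first the point farthest from the
class centroid, then points maximizing the distance to already chosen
centers), so that repeated fits of the same data give identical models.
With one subclass per class the model collapses to linear discriminant
analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp

from .base import (
    ClassifierModel,
    MethodConfig,
    class_index,
    gaussian_logpdf,
    safe_cho_factor,
)


class MIXDAModel(ClassifierModel):
    method = "mixda"

    def __init__(self, classes, means, mixing, covariance, priors, loglik_path, converged):
        # means: (K, R, p); mixing: (K, R)
        super().__init__(classes, means.shape[2])
        self.means_ = means
        self.mixing_ = mixing
        self.covariance_ = covariance
        self.priors_ = priors
        self.loglik_path_ = np.asarray(loglik_path)
        self.converged_ = converged
        self._cho = safe_cho_factor(covariance, "MIXDA")

    def _component_logpdf(self, X: np.ndarray) -> np.ndarray:
        """(n, K, R) log densities of every subclass component."""
        K, R, _ = self.means_.shape
        out = np.empty((len(X), K, R))
        for k in range(K):
            for r in range(R):
                out[:, k, r] = gaussian_logpdf(X, self.means_[k, r], self._cho)
        return out

    def class_log_density(self, X: np.ndarray) -> np.ndarray:
        comp = self._component_logpdf(X)
        with np.errstate(divide="ignore"):
            logmix = np.log(self.mixing_)
        return logsumexp(comp + logmix[None, :, :], axis=2)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        log_post = self.class_log_density(X) + np.log(self.priors_)[None, :]
        return np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))

    def subclass_responsibilities(
        self, X: np.ndarray, y: np.ndarray | None = None
    ) -> np.ndarray:
        """Posterior subclass memberships, shape ``(n, R)``.

        With known class labels ``y`` the responsibilities are computed
        within each observation's own class; otherwise they are obtained
        from the most probable class.
        """
        X = self._check_X(X)
        comp = self._component_logpdf(X)
        with np.errstate(divide="ignore"):
            logmix = np.log(self.mixing_)
        num = comp + logmix[None, :, :]
        if y is None:
            kidx = np.argmax(self.predict_proba(X), axis=1)
        else:
            kidx = np.searchsorted(self.classes_, np.asarray(y))
        rows = num[np.arange(len(X)), kidx, :]
        return np.exp(rows - logsumexp(rows, axis=1, keepdims=True))


def _farthest_point_centers(Xk: np.ndarray, R: int) -> np.ndarray:
    centers = [Xk[np.argmax(np.sum((Xk - Xk.mean(axis=0)) ** 2, axis=1))]]
    while len(centers) < R:
        d = np.min(
            [np.sum((Xk - c) ** 2, axis=1) for c in centers], axis=0
        )
        centers.append(Xk[np.argmax(d)])
    return np.asarray(centers)


def fit_mixda(train, config: MethodConfig | None = None) -> MIXDAModel:
    """Fit the Gaussian-subclass mixture discriminant model by EM."""
    config = config or MethodConfig()
    cfg = config.mixda
    R = cfg.subclasses_per_class
    X = np.asarray(train.X, dtype=float)
    classes, yidx = class_index(train.y_group)
    K = len(classes)
    n, p = X.shape
    class_rows = [np.where(yidx == k)[0] for k in range(K)]
    for k, rows in enumerate(class_rows):
        if len(rows) < R:
            raise ValueError(
                f"class {classes[k]} has {len(rows)} rows, fewer than "
                f"{R} subclasses"
            )
    priors = np.array([len(rows) / n for rows in class_rows])

    # deterministic initialization: farthest-point centers, hard assignment
    means = np.empty((K, R, p))
    mixing = np.full((K, R), 1.0 / R)
    resp = [np.zeros((len(rows), R)) for rows in class_rows]
    for k, rows in enumerate(class_rows):
        Xk = X[rows]
        centers = _farthest_point_centers(Xk, R)
        d2 = ((Xk[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        hard = np.argmin(d2, axis=1)
        resp[k][np.arange(len(rows)), hard] = 1.0

    def m_step():
        nonlocal means, mixing
        S = np.zeros((p, p))
        for k, rows in enumerate(class_rows):
            Xk = X[rows]
            gamma = resp[k]
            mass = gamma.sum(axis=0)
            for r in range(R):
                if mass[r] < 1e-8:
                    # re-seed a starved subclass from the farthest in-class point
                    far = np.argmax(
                        np.min(((Xk[:, None, :] - means[k][None, :, :]) ** 2).sum(axis=2), axis=1)
                    )
                    means[k, r] = Xk[far]
                    mass[r] = 1e-8
                    warnings.warn(
                        f"MIXDA: empty subclass re-seeded in class {classes[k]}",
                        stacklevel=3,
                    )
                else:
                    means[k, r] = gamma[:, r] @ Xk / mass[r]
                d = Xk - means[k, r]
                S += (d * gamma[:, [r]]).T @ d
            mixing[k] = mass / mass.sum()
        return S / n

    cov = m_step()
    loglik_path = []
    ll = -np.inf
    converged = False
    for _ in range(cfg.em_max_iterations):
        cho = safe_cho_factor(cov, "MIXDA")
        new_ll = 0.0
        # E-step within each class
        for k, rows in enumerate(class_rows):
            Xk = X[rows]
            with np.errstate(divide="ignore"):
                num = np.column_stack(
                    [
                        np.log(max(mixing[k, r], 1e-300))
                        + gaussian_logpdf(Xk, means[k, r], cho)
                        for r in range(R)
                    ]
                )
            lse = logsumexp(num, axis=1)
            new_ll += float(lse.sum()) + len(rows) * float(np.log(priors[k]))
            resp[k] = np.exp(num - lse[:, None])
        loglik_path.append(new_ll)
        if np.isfinite(ll) and abs(new_ll - ll) <= cfg.em_tolerance * abs(ll):
            ll = new_ll
            converged = True
            break
        ll = new_ll
        cov = m_step()
    if not converged:
        warnings.warn("MIXDA EM reached the iteration cap before converging", stacklevel=2)
    return MIXDAModel(classes, means, mixing, cov, priors, loglik_path, converged)
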