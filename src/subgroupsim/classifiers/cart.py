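"""Classification tree grown by greedy deviance splitting.

Node deviance is ``-2 * sum_k n_k * log(n_k / n)`` (the multinomial
log-likelihood scaled by -2, with ``0 * log 0 := 0``).  A binary split on
``x_j <= t`` is accepted only when both children contain at least
``min_node_size`` rows and the deviance reduction is at least
``min_deviance_fraction`` times the *root* deviance, which makes the
stopping rule invariant to sample size rescaling of the deviance.  Leaves
predict their majority class and report class proportions as posteriors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .base import ClassifierModel, MethodConfig, class_index

logger = logging.getLogger(__name__)


def node_deviance(counts: np.ndarray) -> float:
    """Deviance of a node with the given class counts."""
    n = counts.sum()
    if n == 0:
        return 0.0
    return float(2.0 * (xlogy(n, n) - xlogy(counts, counts).sum()))


@dataclass
class _Node:
    counts: np.ndarray
    feature: int = -1
    threshold: float = np.nan
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _best_split(X: np.ndarray, yidx: np.ndarray, K: int, min_node: int):
    """Exhaustive greedy search for the best allowed split of one node.

    Returns ``(reduction, feature, threshold)`` or ``None``.  Ties are
    broken to the lowest feature index, then the lowest threshold (the
    first strictly better candidate encountered wins).
    """
    n, p = X.shape
    if n < 2 * min_node:
        return None
    parent_counts = np.bincount(yidx, minlength=K)
    d_parent = node_deviance(parent_counts)
    if d_parent <= 0.0:
        return None
    best = None
    best_red = 0.0
    n_log_n = xlogy(np.arange(n + 1), np.arange(n + 1))
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = yidx[order]
        onehot = np.zeros((n, K))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)  # cum[i] = counts of rows 0..i
        # candidate split after position i (left has i+1 rows)
        pos = np.arange(min_node - 1, n - min_node)
        pos = pos[xs[pos] < xs[pos + 1]]
        if len(pos) == 0:
            continue
        left = cum[pos]
        right = parent_counts[None, :] - left
        nl = pos + 1
        nr = n - nl
        d_left = 2.0 * (n_log_n[nl] - xlogy(left, left).sum(axis=1))
        d_right = 2.0 * (n_log_n[nr] - xlogy(right, right).sum(axis=1))
        red = d_parent - d_left - d_right
        i = int(np.argmax(red))
        if red[i] > best_red + 1e-12:
            best_red = float(red[i])
            best = (best_red, j, float(0.5 * (xs[pos[i]] + xs[pos[i] + 1])))
    return best


def _grow(X, yidx, K, min_node, min_reduction) -> _Node:
    node = _Node(counts=np.bincount(yidx, minlength=K))
    found = _best_split(X, yidx, K, min_node)
    if found is None or found[0] < min_reduction:
        return node
    _, j, t = found
    mask = X[:, j] <= t
    node.feature, node.threshold = j, t
    node.left = _grow(X[mask], yidx[mask], K, min_node, min_reduction)
    node.right = _grow(X[~mask], yidx[~mask], K, min_node, min_reduction)
    return node


class CARTModel(ClassifierModel):
    method = "cart"

    def __init__(self, classes, root: _Node, n_features: int):
        super().__init__(classes, n_features)
        self.root_ = root

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        out = np.empty((len(X), len(self.classes_)))

        def fill(node: _Node, rows: np.ndarray) -> None:
            if len(rows) == 0:
                return
            if node.is_leaf:
                out[rows] = node.counts / node.counts.sum()
                return
            mask = X[rows, node.feature] <= node.threshold
            fill(node.left, rows[mask])
            fill(node.right, rows[~mask])

        fill(self.root_, np.arange(len(X)))
        return out

    @property
    def n_leaves_(self) -> int:
        def count(node: _Node) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root_)


def fit_cart(train, config: MethodConfig | None = None) -> CARTModel:
    """Grow a deviance-split classification tree on the training set."""
    config = config or MethodConfig()
    min_node = config.cart.min_node_size
    X = np.asarray(train.X, dtype=float)
    if len(X) < min_node:
        raise ValueError(f"need at least min_node_size={min_node} rows to fit a tree")
    classes, yidx = class_index(train.y_group)
    K = len(classes)
    root_dev = node_deviance(np.bincount(yidx, minlength=K))
    min_reduction = config.cart.min_deviance_fraction * root_dev
    root = _grow(X, yidx, K, min_node, min_reduction)
    if root.is_leaf:
        logger.info("no allowed split at the root; returning a majority-class tree")
    return CARTModel(classes, root, X.shape[1])
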