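"""Mixture-structured multivariate-normal data simulator.

Generates samples for a classification benchmark in which each *known*
group (the label a classifier is trained to predict) is itself a
two-component Gaussian mixture of *latent* subgroups.  All predictors are
standard-normal within a subgroup, share one correlation/covariance
matrix, and group structure enters only through mean shifts:

* adjacent known groups are separated by a standardized mean difference
  ``delta`` on every predictor (group ``g`` has base mean ``(g-1)*delta``);
* within a group the second subgroup is displaced by ``s`` (the subgroup
  separation) on every predictor, toward the neighbouring group for end
  groups and toward the higher group for a middle group.

The default correlation matrix is the published correlation matrix of the
first five WAIS-III subscales, a realistic social-science predictor
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WAIS_CORRELATION",
    "SimulationDesign",
    "PopulationSpec",
    "LabeledDataset",
    "make_population",
    "allocate_sizes",
    "simulate_pair",
]

#: Correlation matrix of the first five WAIS-III subscales, used as the
#: population correlation of the five simulated predictors.
WAIS_CORRELATION = np.array(
    [
        [1.00, 0.76, 0.58, 0.43, 0.39],
        [0.76, 1.00, 0.57, 0.36, 0.49],
        [0.58, 0.57, 1.00, 0.45, 0.74],
        [0.43, 0.36, 0.45, 1.00, 0.69],
        [0.39, 0.49, 0.74, 0.69, 1.00],
    ]
)


class DesignError(ValueError):
    """Raised when a simulation design violates its invariants."""


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the factorial simulation design.

    Parameters
    ----------
    n_groups
        Number of known groups (2 or 3).
    total_n
        Total sample size of one dataset (training and cross-validation
        samples each have this size).
    group_proportions
        Fraction of the sample in each known group; sums to 1.
    subgroup_proportions
        Pair of fractions applied within every group; the first entry is
        the *base* subgroup (the one farthest from the neighbouring
        group); sums to 1.
    group_separation_delta
        Standardized mean difference between adjacent known groups
        (unit-SD scale), applied to every predictor.
    subgroup_separation
        Standardized separation ``s`` between the two subgroup means
        within each group; ``s = 0`` is the homogeneous control.
    n_predictors
        Number of predictors.
    correlation
        Predictor correlation matrix (symmetric, unit diagonal, PSD).
    """

    n_groups: int = 3
    total_n: int = 150
    group_proportions: tuple[float, ...] = None  # type: ignore[assignment]
    subgroup_proportions: tuple[float, float] = (0.5, 0.5)
    group_separation_delta: float = 0.5
    subgroup_separation: float = 0.0
    n_predictors: int = 5
    correlation: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_groups not in (2, 3):
            raise DesignError(f"n_groups must be 2 or 3, got {self.n_groups}")
        if self.total_n < 1:
            raise DesignError("total_n must be at least 1")
        if self.group_proportions is None:
            object.__setattr__(
                self, "group_proportions", tuple([1.0 / self.n_groups] * self.n_groups)
            )
        gp = np.asarray(self.group_proportions, dtype=float)
        if len(gp) != self.n_groups or not np.isclose(gp.sum(), 1.0):
            raise DesignError(
                "group_proportions must have length n_groups and sum to 1"
            )
        if np.any(gp < 0):
            raise DesignError("group_proportions must be nonnegative")
        sp = np.asarray(self.subgroup_proportions, dtype=float)
        if len(sp) != 2 or not np.isclose(sp.sum(), 1.0) or np.any(sp < 0):
            raise DesignError("subgroup_proportions must be two nonnegative fractions summing to 1")
        if self.group_separation_delta < 0:
            raise DesignError("group separation delta must be nonnegative")
        if self.subgroup_separation < 0:
            raise DesignError("subgroup separation must be nonnegative")
        if self.correlation is None:
            if self.n_predictors != 5:
                raise DesignError(
                    "a correlation matrix must be supplied when n_predictors != 5"
                )
            object.__setattr__(self, "correlation", WAIS_CORRELATION.copy())
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (self.n_predictors, self.n_predictors):
            raise DesignError("correlation matrix shape does not match n_predictors")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise DesignError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise DesignError("correlation matrix must have unit diagonal")
        object.__setattr__(self, "correlation", corr)
        object.__setattr__(self, "group_proportions", tuple(float(x) for x in gp))
        object.__setattr__(self, "subgroup_proportions", tuple(float(x) for x in sp))

    def replace(self, **kwargs) -> "SimulationDesign":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PopulationSpec:
    """Fully resolved generative model for one design cell.

    ``subgroup_means[g, r]`` is the mean vector of subgroup ``r`` of known
    group ``g`` (0-indexed); ``subgroup_weights`` are the corresponding
    sampling probabilities over all (group, subgroup) cells; ``covariance``
    is shared by every subgroup (equal to the design correlation matrix
    because all population SDs are 1).
    """

    subgroup_means: np.ndarray  # (n_groups, 2, p)
    subgroup_weights: np.ndarray  # (n_groups, 2)
    covariance: np.ndarray  # (p, p)

    @property
    def n_groups(self) -> int:
        return self.subgroup_means.shape[0]


@dataclass
class LabeledDataset:
    """Predictor matrix with known-group and latent-subgroup labels.

    ``y_group`` (1-indexed) is visible to classifiers; ``y_subgroup``
    (1 or 2) is the latent mixture component, kept only for diagnostics.
    """

    X: np.ndarray
    y_group: np.ndarray
    y_subgroup: np.ndarray
    role: str = "train"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y_group = np.asarray(self.y_group, dtype=int)
        self.y_subgroup = np.asarray(self.y_subgroup, dtype=int)
        n = self.X.shape[0]
        if len(self.y_group) != n or len(self.y_subgroup) != n:
            raise ValueError("label vectors must match the number of rows of X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.X, columns=[f"x{j + 1}" for j in range(self.X.shape[1])]
        )
        df["group"] = self.y_group
        df["subgroup"] = self.y_subgroup
        df["role"] = self.role
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        xcols = [c for c in df.columns if c.startswith("x")]
        role = df["role"].iloc[0] if "role" in df else "train"
        return cls(
            X=df[xcols].to_numpy(float),
            y_group=df["group"].to_numpy(int),
            y_subgroup=df["subgroup"].to_numpy(int),
            role=str(role),
        )


def _subgroup_direction(g: int, n_groups: int) -> int:
    """Displacement direction of the second subgroup of group ``g`` (0-indexed).

    End groups are displaced toward their neighbour (+1 for the lowest
    group, -1 for the highest); a middle group is displaced upward by
    convention.
    """
    if g == n_groups - 1:
        return -1
    return 1


def make_population(design: SimulationDesign) -> PopulationSpec:
    """Resolve a design cell into per-subgroup means, weights and covariance.

    Group ``g`` (1-indexed) has base mean ``(g-1)*delta`` on every
    predictor; its base subgroup sits at the base mean and the second
    subgroup at ``base + s*direction``.
    """
    G, p = design.n_groups, design.n_predictors
    delta, s = design.group_separation_delta, design.subgroup_separation
    means = np.zeros((G, 2, p))
    for g in range(G):
        base = g * delta
        means[g, 0, :] = base
        means[g, 1, :] = base + s * _subgroup_direction(g, G)
    gp = np.asarray(design.group_proportions)
    sp = np.asarray(design.subgroup_proportions)
    weights = gp[:, None] * sp[None, :]
    return PopulationSpec(
        subgroup_means=means,
        subgroup_weights=weights,
        covariance=np.asarray(design.correlation, dtype=float).copy(),
    )


def _largest_remainder(total: int, proportions: np.ndarray) -> np.ndarray:
    """Apportion ``total`` seats to ``proportions`` by largest remainder.

    Ties in the fractional remainders go to the cell with the larger
    target proportion, then to the lower index.
    """
    proportions = np.asarray(proportions, dtype=float)
    quotas = total * proportions
    counts = np.floor(quotas).astype(int)
    leftover = total - counts.sum()
    if leftover > 0:
        remainders = quotas - counts
        # sort by (remainder desc, proportion desc, index asc)
        order = sorted(
            range(len(proportions)),
            key=lambda i: (-remainders[i], -proportions[i], i),
        )
        for i in order[:leftover]:
            counts[i] += 1
    return counts


def allocate_sizes(design: SimulationDesign) -> np.ndarray:
    """Fixed per-(group, subgroup) counts realizing the design proportions.

    Returns an ``(n_groups, 2)`` integer array summing to ``total_n``.
    Group totals are apportioned first, then subgroup counts within each
    group, both by largest remainder with ties resolved toward the larger
    cell.  The larger subgroup share is always given to the base subgroup
    (index 0), the one whose mean is farthest from the neighbouring group.
    """
    gp = np.asarray(design.group_proportions)
    sp = np.asarray(design.subgroup_proportions)
    group_counts = _largest_remainder(design.total_n, gp)
    counts = np.zeros((design.n_groups, 2), dtype=int)
    for g, ng in enumerate(group_counts):
        counts[g] = _largest_remainder(int(ng), sp)
    if np.any(counts == 0):
        warnings.warn(
            "allocation produced an empty (group, subgroup) cell; "
            "classifiers still run but the mixture is degenerate",
            stacklevel=2,
        )
    return counts


def _covariance_factor(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular matrix square root; informative error when non-PSD."""
    cov = 0.5 * (cov + cov.T)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eigvals = np.linalg.eigvalsh(cov)
        raise DesignError(
            "correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eigvals[0]:.3e})"
        ) from None


def _draw(
    pop: PopulationSpec, counts: np.ndarray, factor: np.ndarray, rng: np.random.Generator, role: str
) -> LabeledDataset:
    G, _, p = pop.subgroup_means.shape
    blocks, groups, subgroups = [], [], []
    for g in range(G):
        for r in range(2):
            n_gr = int(counts[g, r])
            if n_gr == 0:
                continue
            z = rng.standard_normal((n_gr, p))
            blocks.append(z @ factor.T + pop.subgroup_means[g, r])
            groups.append(np.full(n_gr, g + 1))
            subgroups.append(np.full(n_gr, r + 1))
    return LabeledDataset(
        X=np.vstack(blocks),
        y_group=np.concatenate(groups),
        y_subgroup=np.concatenate(subgroups),
        role=role,
    )


def simulate_pair(
    design: SimulationDesign, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Draw a paired training / cross-validation sample for one replicate.

    Both datasets are drawn independently from the same resolved
    population with identical fixed per-cell counts; the same
    ``(design, seed)`` always reproduces the same pair bit for bit.
    """
    pop = make_population(design)
    counts = allocate_sizes(design)
    factor = _covariance_factor(pop.covariance)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    train = _draw(pop, counts, factor, rng, "train")
    cv = _draw(pop, counts, factor, rng, "cv")
    return train, cv
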