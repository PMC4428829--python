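"""Mid-rank machinery for two-group multivariate samples.

The nonparametric two-sample framework implemented here compares the
distributions of two groups A and B coordinate by coordinate through the
*relative effect*

    p_AB = P(X_A < X_B) + 0.5 * P(X_A = X_B),

the probability that a random observation from group B exceeds one from
group A, with ties counted half.  A value of 1/2 means no stochastic
tendency between the groups.  All estimators are functions of mid-ranks
(ranks averaged over tie groups), which realize the normalized (mid-)
empirical distribution function and make every downstream statistic
invariant under strictly increasing marginal transforms.

This module holds the sample container, mid-rank computation, empirical
relative effects / Mann-Whitney functionals, and the cross-group rank
*placements* that feed the studentizing covariance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "InvalidInputError",
    "TwoGroupSample",
    "RelativeEffects",
    "Placements",
    "midranks",
    "relative_effects",
    "placements",
]


class InvalidInputError(ValueError):
    """Input data violate the two-group model's requirements."""


@dataclass(frozen=True)
class TwoGroupSample:
    """An N x d observation matrix with a two-level group label per row.

    Parameters
    ----------
    values
        Real matrix of shape (N, d); rows are observational units,
        columns are coordinates (e.g. CpG loci carrying methylation
        beta-values, or derived immune parameters).
    group
        Length-N array of labels, each ``"A"`` or ``"B"``.  Group A is
        the reference of the relative effect p_AB.
    coord_names
        Optional d coordinate identifiers; defaults to ``c1..cd``.
    """

    values: np.ndarray
    group: np.ndarray
    coord_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.ndim != 2 or values.shape[1] < 1:
            raise InvalidInputError("values must be an N x d matrix with d >= 1")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("values must be finite with no missing entries")
        group = np.asarray(self.group)
        if group.shape != (values.shape[0],):
            raise InvalidInputError("group must have one label per row of values")
        group = group.astype(str)
        labels = set(group.tolist())
        if not labels <= {"A", "B"}:
            raise InvalidInputError(f"group labels must be 'A'/'B', got {sorted(labels)}")
        n_a = int(np.sum(group == "A"))
        n_b = int(np.sum(group == "B"))
        if n_a < 2 or n_b < 2:
            raise InvalidInputError(f"each group needs >= 2 units (n_A={n_a}, n_B={n_b})")
        names = tuple(self.coord_names) or tuple(f"c{j + 1}" for j in range(values.shape[1]))
        if len(names) != values.shape[1]:
            raise InvalidInputError("coord_names must have one entry per coordinate")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "coord_names", names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def a_mask(self) -> np.ndarray:
        return self.group == "A"

    @property
    def b_mask(self) -> np.ndarray:
        return self.group == "B"

    @property
    def n_a(self) -> int:
        return int(np.sum(self.a_mask))

    @property
    def n_b(self) -> int:
        return int(np.sum(self.b_mask))

    def restrict(self, subset) -> "TwoGroupSample":
        """Return the sample restricted to the coordinates in ``subset`` (0-based)."""
        subset = list(subset)
        if len(subset) == 0:
            raise InvalidInputError("subset must be non-empty")
        return TwoGroupSample(
            self.values[:, subset],
            self.group,
            tuple(self.coord_names[j] for j in subset),
        )

    def a_first(self) -> "TwoGroupSample":
        """Reorder rows so all group-A units precede all group-B units."""
        order = np.concatenate([np.flatnonzero(self.a_mask), np.flatnonzero(self.b_mask)])
        return TwoGroupSample(self.values[order], self.group[order], self.coord_names)

    def swap_groups(self) -> "TwoGroupSample":
        """Exchange the A/B labels (maps p_AB to 1 - p_AB)."""
        flipped = np.where(self.group == "A", "B", "A")
        return TwoGroupSample(self.values, flipped, self.coord_names)


@dataclass(frozen=True)
class RelativeEffects:
    """Coordinate-wise estimated relative effects and Mann-Whitney values.

    ``p_hat[l]`` estimates p_AB for coordinate l; ``u_hat = 1 - p_hat``
    under the mid-rank (half-weight-at-ties) kernel used throughout.
    """

    p_hat: np.ndarray
    u_hat: np.ndarray


@dataclass(frozen=True)
class Placements:
    """Cross-group normalized-ecdf transforms of each observation.

    ``y_a[k, l]`` is the mid-ecdf of group B's coordinate l evaluated at
    the k-th A observation, and symmetrically for ``y_b``.  Column means
    of ``y_b`` equal p_hat and column means of ``y_a`` equal 1 - p_hat.
    These are the building blocks of the studentizing covariance.
    """

    y_a: np.ndarray
    y_b: np.ndarray


def midranks(x) -> np.ndarray:
    """Mid-ranks of a vector: ordinary ranks averaged over each tie group.

    The sum of the output is always n(n+1)/2.  Evaluating the normalized
    empirical cdf at a sample point x_k gives (midrank_k - 1/2) / n.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise InvalidInputError("midranks expects a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("midranks requires finite values")
    return rankdata(x, method="average")


def relative_effects(sample: TwoGroupSample) -> RelativeEffects:
    """Estimate the vector of relative effects from pooled mid-ranks.

    For each coordinate, p_hat = (Rbar_B - (n_B + 1)/2) / n_A where
    Rbar_B is the mean pooled mid-rank of the group-B observations.
    This equals the pairwise-kernel average
    (1 / n_A n_B) sum_j sum_k [ I{x_Aj < x_Bk} + 0.5 I{x_Aj = x_Bk} ].
    """
    pooled = rankdata(sample.values, method="average", axis=0)
    rbar_b = pooled[sample.b_mask].mean(axis=0)
    p_hat = (rbar_b - (sample.n_b + 1) / 2.0) / sample.n_a
    return RelativeEffects(p_hat=p_hat, u_hat=1.0 - p_hat)


def placements(sample: TwoGroupSample) -> Placements:
    """Rank placements: pooled minus within-group mid-ranks, normalized.

    y_Ak = (pooled rank of x_Ak - within-A rank of x_Ak) / n_B evaluates
    the group-B mid-ecdf at x_Ak without a second pass over the data;
    symmetrically for group B.
    """
    v = sample.values
    pooled = rankdata(v, method="average", axis=0)
    a, b = sample.a_mask, sample.b_mask
    within_a = rankdata(v[a], method="average", axis=0)
    within_b = rankdata(v[b], method="average", axis=0)
    y_a = (pooled[a] - within_a) / sample.n_b
    y_b = (pooled[b] - within_b) / sample.n_a
    return Placements(y_a=y_a, y_b=y_b)
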