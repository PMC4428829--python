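"""Placement-based estimation of the studentizing covariance matrix.

The d-dimensional vector of empirical relative effects, centered and
scaled by sqrt(N), is asymptotically multivariate normal with covariance

    V(l, r) = (N / n_A) c_A(l, r) + (N / n_B) c_B(l, r),

where c_i is the covariance of the cross-group cdf transforms within
group i.  The empirical counterpart replaces c_i by the sample
covariance (divisor n_i - 1) of the rank-placement columns of group i.
The same engine studentizes both the relative-effect statistic and the
Mann-Whitney statistic: under the half-weight tie kernel the two
population matrices coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ranks import InvalidInputError, Placements

__all__ = ["CovarianceEstimate", "covariance_estimate", "studentizing_inverse"]

#: Relative eigenvalue tolerance below which a direction is treated as flat.
PINV_RTOL = 1e-10


@dataclass(frozen=True)
class CovarianceEstimate:
    """Symmetric PSD d x d studentizing matrix with rank bookkeeping.

    ``degenerate`` flags coordinates whose placements have zero variance
    in *both* groups (e.g. complete separation); such coordinates drive
    rank deficiency downstream but never raise.
    """

    v_hat: np.ndarray
    n_a: int
    n_b: int
    rank: int
    degenerate: np.ndarray

    @property
    def n(self) -> int:
        return self.n_a + self.n_b


def _column_cov(y: np.ndarray) -> np.ndarray:
    """Sample covariance (divisor n-1) of the columns of an n x d matrix."""
    n = y.shape[0]
    centered = y - y.mean(axis=0)
    return centered.T @ centered / (n - 1)


def covariance_estimate(pl: Placements, n_a: int, n_b: int) -> CovarianceEstimate:
    """Build V_hat = (N/n_A) c_A + (N/n_B) c_B from rank placements."""
    if n_a < 2 or n_b < 2:
        raise InvalidInputError("covariance estimation needs n_A, n_B >= 2")
    c_a = _column_cov(pl.y_a)
    c_b = _column_cov(pl.y_b)
    n = n_a + n_b
    v_hat = (n / n_a) * c_a + (n / n_b) * c_b
    v_hat = (v_hat + v_hat.T) / 2.0
    degenerate = (np.diag(c_a) == 0.0) & (np.diag(c_b) == 0.0)
    eigvals = np.linalg.eigvalsh(v_hat)
    tol = PINV_RTOL * max(eigvals.max(), 0.0)
    rank = int(np.sum(eigvals > tol))
    return CovarianceEstimate(v_hat=v_hat, n_a=n_a, n_b=n_b, rank=rank, degenerate=degenerate)


def studentizing_inverse(cov: CovarianceEstimate, subset) -> tuple[np.ndarray, int]:
    """Moore-Penrose pseudoinverse of an S x S submatrix of V_hat.

    Returns the pseudoinverse together with the numerical rank of the
    submatrix, which serves as the effective degrees of freedom of the
    quadratic-form statistic.  For a well-conditioned submatrix this is
    the ordinary inverse with effective df = |S|.  A rank-0 submatrix
    yields the zero matrix with df 0 ("undefined statistic" sentinel).

    ``subset`` holds 0-based coordinate indices.
    """
    subset = list(subset)
    if len(subset) == 0:
        raise InvalidInputError("subset must be non-empty")
    sub = cov.v_hat[np.ix_(subset, subset)]
    eigvals, eigvecs = np.linalg.eigh(sub)
    tol = PINV_RTOL * max(eigvals.max(), 0.0)
    keep = eigvals > tol
    inv_vals = np.where(keep, 1.0 / np.where(keep, eigvals, 1.0), 0.0)
    pinv = (eigvecs * inv_vals) @ eigvecs.T
    return pinv, int(np.sum(keep))
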