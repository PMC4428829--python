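"""Wald-type quadratic-form statistics and their chi-square calibration.

The global (or subset) hypothesis of no relative effect is tested with

    W_N = N (p_hat - 1/2)' V_hat^{-1} (p_hat - 1/2),

asymptotically chi-square with |S| degrees of freedom on a coordinate
subset S (effective rank when V_hat is degenerate).  The companion
Mann-Whitney family tests marginal homogeneity with u_hat = 1 - p_hat;
under the half-weight tie kernel the two statistics coincide
numerically, but both names are kept because the hypothesis families
differ and the permutation null is finite-sample exact only under
homogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .covariance import CovarianceEstimate, covariance_estimate, studentizing_inverse
from .ranks import (
    InvalidInputError,
    RelativeEffects,
    TwoGroupSample,
    placements,
    relative_effects,
)

__all__ = ["TestResult", "wald_statistic", "chi2_pvalue", "asymptotic_test"]

STAT_FAMILIES = ("relative_effect", "wmw")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a quadratic-form test on a coordinate subset."""

    statistic: float
    effective_df: int
    p_asymptotic: float
    subset: tuple[int, ...]
    stat_family: str
    calibration: str
    p_permutation: float | None = None


def wald_statistic(
    effects: RelativeEffects,
    cov: CovarianceEstimate,
    subset=None,
    stat_family: str = "relative_effect",
) -> tuple[float, int]:
    """Quadratic form N (v - 1/2)' M (v - 1/2) on the subset S.

    ``v`` is p_hat (relative-effect family) or u_hat (Mann-Whitney
    family) and M the studentizing pseudoinverse of the S-submatrix of
    V_hat.  Returns the statistic and the effective degrees of freedom.
    """
    if stat_family not in STAT_FAMILIES:
        raise InvalidInputError(f"unknown stat_family {stat_family!r}")
    d = cov.v_hat.shape[0]
    subset = list(range(d)) if subset is None else list(subset)
    v = effects.p_hat if stat_family == "relative_effect" else effects.u_hat
    diff = v[subset] - 0.5
    pinv, df = studentizing_inverse(cov, subset)
    stat = float(cov.n * diff @ pinv @ diff)
    return max(stat, 0.0), df


def chi2_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability; df = 0 returns 1 (no evidence)."""
    if df < 0:
        raise InvalidInputError("degrees of freedom must be >= 0")
    if df == 0:
        return 1.0
    return float(chi2.sf(statistic, df))


def asymptotic_test(
    sample: TwoGroupSample,
    subset=None,
    stat_family: str = "relative_effect",
) -> TestResult:
    """Chi-square-calibrated test of the (subset) global null on a sample."""
    subset = tuple(range(sample.d)) if subset is None else tuple(subset)
    effects = relative_effects(sample)
    cov = covariance_estimate(placements(sample), sample.n_a, sample.n_b)
    stat, df = wald_statistic(effects, cov, subset, stat_family)
    return TestResult(
        statistic=stat,
        effective_df=df,
        p_asymptotic=chi2_pvalue(stat, df),
        subset=subset,
        stat_family=stat_family,
        calibration="chi2",
    )
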