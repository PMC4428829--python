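"""Two-stage screen/confirm pipeline for large locus families.

Full closed testing is exponential in d, so genome-scale methylation
studies are handled in two statistically independent stages on disjoint
subject sub-samples: a *screening* stage ranks all loci by univariate
two-sample Wilcoxon p-values and carries the top m forward, and a
*confirmation* stage runs the closed multivariate (permutation) test on
those m loci only.  Because the stages use disjoint observational
units, the confirmation-stage adjusted p-values are valid at face value
despite the data-driven selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .closure import ClosedTestResult, closed_test
from .permutation import PermutationPlan
from .ranks import InvalidInputError, TwoGroupSample

__all__ = ["TwoStagePlan", "split", "screen", "confirm", "two_stage_pipeline"]


@dataclass(frozen=True)
class TwoStagePlan:
    """Sample-split fractions per group, loci carried forward, and split seed."""

    screen_fraction_a: float = 2 / 3
    screen_fraction_b: float = 2 / 3
    m: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.screen_fraction_a < 1 and 0 < self.screen_fraction_b < 1):
            raise InvalidInputError("screen fractions must lie strictly in (0, 1)")
        if self.m < 1:
            raise InvalidInputError("m must be >= 1")


def split(sample: TwoGroupSample, plan: TwoStagePlan) -> tuple[TwoGroupSample, TwoGroupSample]:
    """Random within-group split into disjoint screening and confirmation samples.

    The screening sample receives round(fraction * n_group) units of each
    group; both stages must retain at least two units per group.
    """
    rng = np.random.default_rng(plan.seed)
    screen_rows, confirm_rows = [], []
    for label, frac in (("A", plan.screen_fraction_a), ("B", plan.screen_fraction_b)):
        idx = np.flatnonzero(sample.group == label)
        n_screen = int(round(frac * idx.size))
        if n_screen < 2 or idx.size - n_screen < 2:
            raise InvalidInputError(
                f"group {label}: split leaves fewer than 2 units in a stage "
                f"({n_screen} screening of {idx.size})"
            )
        chosen = rng.choice(idx, size=n_screen, replace=False)
        mask = np.zeros(sample.n, dtype=bool)
        mask[chosen] = True
        screen_rows.append(np.flatnonzero(mask))
        confirm_rows.append(np.setdiff1d(idx, chosen))
    s_idx = np.sort(np.concatenate(screen_rows))
    c_idx = np.sort(np.concatenate(confirm_rows))
    make = lambda rows: TwoGroupSample(sample.values[rows], sample.group[rows], sample.coord_names)
    return make(s_idx), make(c_idx)


def screen(sample: TwoGroupSample, m: int) -> list[tuple[int, float]]:
    """Univariate Wilcoxon screening: the m smallest p-value coordinates.

    Per-coordinate two-sided Wilcoxon rank-sum p-values (exact for small
    untied samples, normal approximation with tie correction otherwise);
    ties in the p-value ranking break stably by coordinate index.
    Returns (coordinate index, p-value) pairs in ascending p order.
    """
    if m > sample.d:
        raise InvalidInputError(f"cannot select m={m} of d={sample.d} coordinates")
    xa = sample.values[sample.a_mask]
    xb = sample.values[sample.b_mask]
    pvals = np.array(
        [mannwhitneyu(xa[:, j], xb[:, j], alternative="two-sided").pvalue for j in range(sample.d)]
    )
    order = np.argsort(pvals, kind="stable")[:m]
    return [(int(j), float(pvals[j])) for j in order]


def confirm(
    confirm_sample: TwoGroupSample,
    selected,
    alpha: float = 0.05,
    plan: PermutationPlan | None = None,
    calibration: str = "permutation",
) -> ClosedTestResult:
    """Closed multivariate test of the selected loci on the confirmation sample."""
    indices = [s[0] if isinstance(s, tuple) else int(s) for s in selected]
    restricted = confirm_sample.restrict(indices)
    return closed_test(restricted, alpha, calibration=calibration, plan=plan)


def two_stage_pipeline(
    sample: TwoGroupSample,
    stage_plan: TwoStagePlan,
    perm_plan: PermutationPlan | None = None,
    alpha: float = 0.05,
    calibration: str = "permutation",
) -> tuple[list[tuple[int, float]], ClosedTestResult]:
    """Split, screen and confirm in one call; returns (selection, closed-test result)."""
    screen_sample, confirm_sample = split(sample, stage_plan)
    selected = screen(screen_sample, stage_plan.m)
    result = confirm(confirm_sample, selected, alpha, perm_plan, calibration)
    return selected, result
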