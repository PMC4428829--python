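"""Permutation plan, tau centering, permuted statistic and p-values."""

import numpy as np
import pytest
from scipy.stats import chi2, kstest

from releff import (
    PermutationNull,
    PermutationPlan,
    TwoGroupSample,
    permutation_centering,
    permutation_pvalue,
    permutation_test,
    permuted_statistic,
    relative_effects,
    tau_fraction,
)
from releff.permutation import _batch_moments, _null_for_subset
from releff.ranks import InvalidInputError

from conftest import brute_force_relative_effect, make_sample, mid_ecdf


def test_plan_realizes_valid_permutations():
    plan = PermutationPlan(n_perm=25, seed=3)
    perms = plan.permutations(12)
    assert perms.shape == (26, 12)  # identity appended
    np.testing.assert_array_equal(perms[-1], np.arange(12))
    for row in perms:
        np.testing.assert_array_equal(np.sort(row), np.arange(12))


def test_plan_reproducible_bit_for_bit():
    a = PermutationPlan(50, seed=9).permutations(10)
    b = PermutationPlan(50, seed=9).permutations(10)
    np.testing.assert_array_equal(a, b)


@pytest.mark.parametrize(
    "perm, n_a, n_b, expected",
    [
        (np.arange(5), 2, 3, 0.0),
        ([2, 3, 0, 1], 2, 2, 1.0),  # full group swap
        ([0, 2, 1, 3, 4], 2, 3, 0.5),  # front block {A1, B1}
    ],
)
def test_tau_fraction_counts_moved_units(perm, n_a, n_b, expected):
    assert tau_fraction(perm, n_a, n_b) == expected


def test_tau_fraction_rejects_non_permutation():
    with pytest.raises(InvalidInputError):
        tau_fraction([0, 0, 1, 2], 2, 2)


def test_centering_identity_swap_and_fixed_point():
    p_hat = np.array([0.3, 0.8])
    np.testing.assert_allclose(permutation_centering(0.0, 4, 6, p_hat), p_hat)
    np.testing.assert_allclose(permutation_centering(1.0, 5, 5, p_hat), 1 - p_hat)
    half = np.full(3, 0.5)
    np.testing.assert_allclose(permutation_centering(0.37, 4, 6, half), half)


def test_centering_is_conditional_mean_of_permuted_effect(rng):
    """E[p_hat^pi | tau] equals the tau-mixture centering, exactly."""
    values = rng.random((10, 1))
    sample = TwoGroupSample(values, np.array(["A"] * 4 + ["B"] * 6)).a_first()
    p_hat = relative_effects(sample).p_hat
    perms = PermutationPlan(20000, seed=2, include_identity=False).permutations(10)
    p_pi, _, _, tau = _batch_moments(sample.values, 4, perms)
    for t in np.unique(tau):
        sel = tau == t
        if sel.sum() < 500:
            continue
        expected = permutation_centering(float(t), 4, 6, p_hat)
        mc_se = p_pi[sel, 0].std() / np.sqrt(sel.sum())
        assert p_pi[sel, 0].mean() == pytest.approx(expected[0], abs=max(4 * mc_se, 1e-12))


def test_identity_permutation_statistic_is_zero(small_sample):
    assert permuted_statistic(small_sample, np.arange(10)) == pytest.approx(0.0, abs=1e-12)


def test_permuted_statistic_matches_brute_force_oracle():
    """Fixed permutation on a 3+3 sample reproduced by an independent oracle."""
    sample = make_sample([1, 2, 3], [4, 5, 6])
    perm = np.array([4, 1, 3, 0, 5, 2])
    # oracle: rebuild pseudo-groups explicitly and evaluate the quadratic form
    pooled = sample.values[perm, 0]
    pa, pb = pooled[:3], pooled[3:]
    p_pi = brute_force_relative_effect(pa, pb)
    y_a = np.array([mid_ecdf(pb, x) for x in pa])
    y_b = np.array([mid_ecdf(pa, x) for x in pb])
    v_pi = 2 * np.var(y_a, ddof=1) + 2 * np.var(y_b, ddof=1)
    tau = np.mean(perm[:3] >= 3)
    for centering, p_ref in (
        ("estimated", relative_effects(sample).p_hat[0]),
        ("null", 0.5),
    ):
        c = permutation_centering(tau, 3, 3, np.array([p_ref]))[0]
        expected = 6 * (p_pi - c) ** 2 / v_pi
        got = permuted_statistic(sample, perm, centering=centering)
        assert got == pytest.approx(expected), centering


def test_pvalue_conventions():
    null = PermutationNull(np.array([0.0, 1.0, 2.0, 3.0]), np.zeros(4))
    assert permutation_pvalue(2.0, null) == 0.5
    assert permutation_pvalue(0.0, null) == 1.0
    assert permutation_pvalue(99.0, null) == 0.25  # floored at 1/(B+1)
    excl = PermutationNull(np.array([1.0, 2.0, 3.0]), np.zeros(3), identity_included=False)
    assert permutation_pvalue(2.5, excl) == pytest.approx(2 / 4)  # +1/+1 rule


def test_pvalue_floor_equals_plan_granularity():
    # near-complete separation with one overlapping pair per coordinate,
    # so the covariance stays non-degenerate and the statistic is huge
    col = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5,
                    0.45, 0.55, 0.65, 0.75, 0.85, 0.95])
    values = np.column_stack([col, col[::-1] * -1])
    sample = TwoGroupSample(values, np.array(["A"] * 6 + ["B"] * 6))
    res = permutation_test(sample, PermutationPlan(199, seed=1))
    assert res.p_permutation == pytest.approx(1 / 200)


def test_fully_separated_sample_reports_no_evidence():
    """Complete separation degenerates the covariance: the statistic is
    undefined and the test refuses to claim significance."""
    values = np.tile(np.arange(12.0)[:, None], (1, 2))
    sample = TwoGroupSample(values, np.array(["A"] * 6 + ["B"] * 6))
    res = permutation_test(sample, PermutationPlan(199, seed=1))
    assert res.effective_df == 0
    assert res.p_asymptotic == 1.0


def test_permutation_test_reproducible(small_sample):
    r1 = permutation_test(small_sample, PermutationPlan(299, seed=17))
    r2 = permutation_test(small_sample, PermutationPlan(299, seed=17))
    assert r1.p_permutation == r2.p_permutation


def test_null_cdf_approaches_chi2(rng):
    """KS distance between the permutation null and chi2_d shrinks with N."""
    distances = {}
    for n_a, n_b in ((24, 36), (80, 120), (240, 360)):
        values = rng.random((n_a + n_b, 2))
        sample = TwoGroupSample(values, np.array(["A"] * n_a + ["B"] * n_b))
        null = _null_for_subset(sample, PermutationPlan(999, seed=5), (0, 1))
        distances[n_a + n_b] = kstest(null.w_values, chi2(2).cdf).statistic
    assert distances[200] < 0.08
    assert distances[600] < distances[60]


def test_permutation_pvalue_superuniform_under_exchangeability():
    """P(p <= alpha) stays near alpha + 1/(B+1) when both groups share a law."""
    n_sim, b = 2000, 199
    hits = 0
    for k in range(n_sim):
        rng = np.random.default_rng(31000 + k)
        values = rng.standard_normal((30, 2))
        sample = TwoGroupSample(values, np.array(["A"] * 12 + ["B"] * 18))
        res = permutation_test(sample, PermutationPlan(b, seed=int(rng.integers(2**31))))
        hits += res.p_permutation <= 0.05
    bound = 0.05 + 1 / (b + 1)
    assert hits / n_sim <= bound + 3 * np.sqrt(bound * (1 - bound) / n_sim)


def test_estimated_centering_exposed_in_test_pipeline(small_sample):
    """Both centerings run end to end and give valid p-values."""
    plan = PermutationPlan(199, seed=8)
    for centering in ("null", "estimated"):
        res = permutation_test(small_sample, plan, centering=centering)
        assert 0 < res.p_permutation <= 1
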