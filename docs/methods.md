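# Methods

## Model and estimands

Two groups A and B contribute n_A and n_B independent d-dimensional
observation vectors (N = n_A + n_B); within a group the vectors are iid
with arbitrary (possibly different) multivariate distributions.  The
estimand at coordinate ℓ is the relative effect
p_AB^(ℓ) = P(X_A^(ℓ) < X_B^(ℓ)) + ½P(X_A^(ℓ) = X_B^(ℓ)), and the
coordinate-wise hypotheses are H′_ℓ : p_AB^(ℓ) = ½ against two-sided
alternatives.  A companion family (marginal homogeneity,
H_ℓ : F_A^(ℓ) = F_B^(ℓ)) is carried by the Mann–Whitney functional
u = 1 − p; both families share one computational engine.

## Tie handling

All estimators use mid-ranks — equivalently the normalized (mid-)
empirical cdf, which gives weight ½ to ties.  Under this kernel
û = 1 − p̂ holds identically (not only for continuous laws), the
group-swap antisymmetry p̂ ↦ 1 − p̂ is exact, and every statistic is
invariant under strictly increasing marginal transforms.  Rounded
β-values therefore never produce undefined results.  Ranks are computed
per coordinate with a single stable sorting pass; coordinates are never
pooled.

## Estimators

- p̂_AB^(ℓ) = (R̄_B^(ℓ) − (n_B+1)/2)/n_A from pooled mid-ranks; equal to
  the pairwise kernel average (verified against brute-force enumeration
  on all small tied samples in the test suite).
- Placements y_Ak = (pooled rank − within-A rank)/n_B evaluate the
  cross-group mid-ecdf at each observation; their column means are
  1 − p̂ and p̂ exactly.
- Studentizing covariance V̂ = (N/n_A)ĉ_A + (N/n_B)ĉ_B, with ĉ_i the
  sample covariance (divisor n_i − 1) of group i's placement columns.
  The divisor is a free choice at this sample-size order; n_i − 1 is
  conventional and reproduces the reference operating characteristics.
- W_N = N(p̂ − ½1)ᵀ V̂⁻¹ (p̂ − ½1), asymptotically χ² with d degrees of
  freedom; any coordinate subset S uses the S×S submatrix and |S| df.

## Degenerate covariances

A coordinate with zero placement variance in both groups (e.g. complete
separation) flattens V̂.  The inverse is always the Moore–Penrose
pseudoinverse with relative eigenvalue tolerance 1e−10 × largest
eigenvalue; the χ² reference then uses the numerical rank as effective
degrees of freedom.  A rank-0 (sub)matrix yields the sentinel
"statistic 0, df 0, p = 1": no evidence is claimable in flat directions,
which keeps the procedure conservative rather than undefined.  Permuted
statistics use the same rule and are never dropped from the null.

## Permutation calibration

A plan of B random permutations of {1..N} (uniform, with replacement;
default B = 9999) plus the identity is drawn once.  For each permutation
the pooled observations are relabelled into pseudo-groups of sizes n_A
and n_B, and the studentized quadratic form is recomputed with the
mixture centering

    c(τ, p) = τ(1 + n_A/n_B)·½·1_d + (1 − τ(1 + n_A/n_B))·p,

where τ is the fraction of original group-B units among the first n_A
positions.  c(τ, p̂) is exactly the conditional mean of the permuted
estimate given τ (a finite-sample identity, checked in the tests).  The
Monte-Carlo p-value is #{π, identity included : W^π ≥ W_obs}/(B+1),
floored at 1/(B+1) so it is never zero.

Two centerings are exposed:

- `centering="null"` (default): the mixture is evaluated at the tested
  value p = ½, its fixed point, so the permuted statistic is the plain
  studentized quadratic form of the relabelled data.  When the two
  groups are exchangeable this makes the test finite-sample exact, and
  empirically it is slightly conservative at moderate N — the behavior
  reported for this methodology's simulation studies.
- `centering="estimated"`: the mixture is evaluated at the observed p̂
  (the general operational form; the identity permutation then yields
  exactly 0).  This version remains asymptotically valid whatever the
  truth, which matters when the null distribution estimate must hold
  under alternatives.  At moderate N it is measurably liberal under the
  null (empirical size ≈ 0.06 at d = 2, n_A/n_B = 20/30), because
  conditioning the centering on the observed effect removes exactly the
  between-τ variance component from the null in the datasets most likely
  to reject.  The two centerings coincide asymptotically: the mixing
  coefficient τ(1 + n_A/n_B) concentrates at 1, shrinking both centers
  to ½.

The default is the null-value centering for all testing entry points;
the estimated centering is kept for the construction itself and for
users who need a truth-agnostic null approximation.

## Closed testing

All 2^d − 1 subset hypotheses are tested at full level α; coordinate ℓ
is rejected iff every subset containing it is rejected, and its adjusted
p-value is the maximum subset p-value — the smallest FWER level at which
it falls.  One permutation plan (and one batch of permuted rank moments)
is shared across all subsets: the S-restricted permuted covariance is
the S×S block of the full one because all rank quantities are
coordinate-wise.  The induced positive dependence among subset p-values
is harmless for the closure's validity and reduces the cost from
2^d full permutation passes to one.  Full closure is capped at d = 15
(32,767 subsets); larger families must be screened first.

## Two-stage pipeline

For locus families beyond the closure cap, subjects are split once,
within groups, into a screening subsample (default fraction 2/3 per
group, rounded) and a confirmation subsample.  Screening ranks all loci
by univariate two-sided Wilcoxon rank-sum p-values
(`scipy.stats.mannwhitneyu`, exact for small untied samples, normal
approximation with tie correction otherwise — only the ranking matters)
and carries the top m (default 10) forward.  Confirmation runs the
closed permutation test on those m loci using only the held-out
subjects, so the data-driven selection does not invalidate the adjusted
p-values.

## Synthetic data (Model 1)

The generator emulates β-values at d neighbouring CpG loci: marginals
Beta(a, b) with b = 4 and a = 3 for null coordinates in both groups; for
shifted coordinates group B gets a = 3 + δ (stochastically larger).
Dependence is a Gaussian copula with AR(1) correlation ρ^|ℓ−r|
(ρ ∈ [0, 1)), mimicking co-methylation decaying with genomic distance;
the copula is parameterized directly by its correlation matrix, the only
scale-free reading.  Shifted coordinates are the last d − d₀.  What the
generator does **not** emulate: bimodal marginals, measurement error in
the intensity ratio, batch effects, or age confounding — so passing
simulation checks demonstrate the procedures' operating characteristics
under smooth unimodal marginals with stationary dependence, not
robustness to those real-data features (the rank machinery is invariant
to any monotone marginal distortion, which covers much of the gap).

Experiment harnesses estimate type-I error and power of the global test
and the FWER of the closed test as rejection frequencies over K
replicates, with binomial standard errors.  Per-replicate RNG streams
are spawned from the master seed (order-insensitive, fully
reproducible); each replicate's permutation plan is seeded from its
stream.

## Problem sizes and defaults

Reference simulation scales: χ²-calibrated cells K = 10,000 (type-I) or
5,000 (power, FWER); permutation cells K = 2,000 with B = 999 for the
global test and K = 1,000 with B = 499 for the closed test — sizes at
which a binomial 3·SE band resolves the reported rates while keeping a
desk-scale runtime (minutes on one CPU).  Test-pipeline defaults:
α = 0.05, B = 9999, divisor n_i − 1, pseudoinverse tolerance 1e−10,
screening fraction 2/3, m = 10, d_max = 15.

## Known limitations

- No confidence intervals for p_AB; the framework tests only.
- No step-down shortcuts of the closure and no FDR-type error control.
- Two groups only; multi-sample designs are out of scope.
- The permutation test's finite-sample exactness holds under
  exchangeability (marginal homogeneity); under H′ with distinct group
  distributions only the asymptotic guarantee applies.
- Full closure cost grows as 2^d; use the two-stage pipeline beyond
  d = 15.
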