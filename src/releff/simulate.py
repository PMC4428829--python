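"""Model-1 synthetic data and the simulation experiment harnesses.

Model 1 emulates methylation beta-values at d neighbouring loci: each
coordinate has a Beta(a, b) marginal on [0, 1] and the coordinates are
coupled by a Gaussian copula with AR(1) correlation R_{l,r} = rho^|l-r|
(co-methylation decaying with genomic distance).  The second shape
parameter is fixed at b = 4 and the first at a = 3 in both groups for
the d0 "true null" coordinates 1..d0; for the remaining d1 = d - d0
coordinates group A keeps a = 3 while group B gets a = 3 + delta, a
stochastically-larger shape shift of size delta.

Three harnesses estimate operating characteristics over K independent
replicates: the empirical type-I error and power of the global test
(chi-square or permutation calibrated) and the empirical family-wise
error rate of the closed multiple test, each reported with its binomial
standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.special import betaincinv, ndtr

from .closure import closed_test
from .permutation import PermutationPlan, permutation_test
from .ranks import InvalidInputError, TwoGroupSample
from .wald import asymptotic_test

__all__ = [
    "Model1Config",
    "ExperimentResult",
    "generate_model1",
    "type1_experiment",
    "power_experiment",
    "fwer_experiment",
    "experiment_grid",
]


@dataclass(frozen=True)
class Model1Config:
    """All knobs of a Model-1 simulation cell.

    ``d0`` coordinates are true nulls (Beta(3, 4) in both groups); the
    last ``d - d0`` coordinates carry the shape shift delta in group B.
    ``calibration`` selects how the test in each replicate is
    calibrated; ``n_perm`` is the Monte-Carlo permutation count B.
    """

    d: int
    d0: int
    delta: float = 0.0
    rho: float = 0.0
    a_base: float = 3.0
    b_shape: float = 4.0
    n_a: int = 20
    n_b: int = 30
    n_rep: int = 1000
    n_perm: int = 999
    alpha: float = 0.05
    calibration: str = "chi2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1 or not (0 <= self.d0 <= self.d):
            raise InvalidInputError("need d >= 1 and 0 <= d0 <= d")
        if self.delta < 0:
            raise InvalidInputError("delta must be >= 0")
        if not (0 <= self.rho < 1):
            raise InvalidInputError("rho must lie in [0, 1)")
        if min(self.n_a, self.n_b, self.n_rep) < 1:
            raise InvalidInputError("counts must be positive")
        if self.calibration not in ("chi2", "permutation"):
            raise InvalidInputError(f"unknown calibration {self.calibration!r}")


@dataclass(frozen=True)
class ExperimentResult:
    """An empirical rejection rate with its binomial standard error."""

    rate: float
    se: float
    n_rep: int


@lru_cache(maxsize=None)
def _ar1_cholesky(d: int, rho: float) -> np.ndarray:
    r = rho ** np.abs(np.subtract.outer(np.arange(d), np.arange(d)))
    return np.linalg.cholesky(r)


def generate_model1(cfg: Model1Config, rng) -> TwoGroupSample:
    """Draw one two-group sample from Model 1.

    Per unit: a d-variate standard Gaussian with AR(1) correlation is
    mapped through the standard normal cdf to copula uniforms, then
    through the beta quantile function of the coordinate- and
    group-specific shapes.  Rows are ordered A-first.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = cfg.n_a + cfg.n_b
    chol = _ar1_cholesky(cfg.d, float(cfg.rho))
    z = rng.standard_normal((n, cfg.d)) @ chol.T
    u = ndtr(z)
    x = np.empty_like(u)
    a, b = cfg.a_base, cfg.b_shape
    if cfg.d0 > 0:
        x[:, : cfg.d0] = betaincinv(a, b, u[:, : cfg.d0])
    if cfg.d0 < cfg.d:
        x[: cfg.n_a, cfg.d0 :] = betaincinv(a, b, u[: cfg.n_a, cfg.d0 :])
        x[cfg.n_a :, cfg.d0 :] = betaincinv(a + cfg.delta, b, u[cfg.n_a :, cfg.d0 :])
    group = np.array(["A"] * cfg.n_a + ["B"] * cfg.n_b)
    return TwoGroupSample(x, group)


def _replicate_rngs(cfg: Model1Config):
    """Independent, order-insensitive per-replicate streams from the master seed."""
    return [np.random.default_rng(c) for c in np.random.SeedSequence(cfg.seed).spawn(cfg.n_rep)]


def _global_rejects(cfg: Model1Config, rng) -> bool:
    sample = generate_model1(cfg, rng)
    if cfg.calibration == "chi2":
        return asymptotic_test(sample).p_asymptotic <= cfg.alpha
    plan = PermutationPlan(n_perm=cfg.n_perm, seed=int(rng.integers(2**31)))
    return permutation_test(sample, plan).p_permutation <= cfg.alpha


def _rate(hits: int, k: int) -> ExperimentResult:
    rate = hits / k
    return ExperimentResult(rate=rate, se=float(np.sqrt(rate * (1 - rate) / k)), n_rep=k)


def type1_experiment(cfg: Model1Config) -> ExperimentResult:
    """Empirical type-I error of the global test: d0 = d, rejection rate at alpha."""
    if cfg.d0 != cfg.d:
        raise InvalidInputError("type-I experiment requires d0 = d (global null true)")
    hits = sum(_global_rejects(cfg, rng) for rng in _replicate_rngs(cfg))
    return _rate(hits, cfg.n_rep)


def power_experiment(cfg: Model1Config) -> ExperimentResult:
    """Empirical power of the global test: d0 < d with a positive shift delta."""
    if cfg.d0 >= cfg.d:
        raise InvalidInputError("power experiment requires d0 < d")
    if cfg.delta <= 0:
        raise InvalidInputError("power experiment requires delta > 0")
    hits = sum(_global_rejects(cfg, rng) for rng in _replicate_rngs(cfg))
    return _rate(hits, cfg.n_rep)


def fwer_experiment(cfg: Model1Config) -> ExperimentResult:
    """Empirical FWER of the closed test: rejections among the d0 true nulls."""
    if cfg.d0 < 1:
        raise InvalidInputError("FWER experiment requires at least one true null")
    hits = 0
    for rng in _replicate_rngs(cfg):
        sample = generate_model1(cfg, rng)
        plan = None
        if cfg.calibration == "permutation":
            plan = PermutationPlan(n_perm=cfg.n_perm, seed=int(rng.integers(2**31)))
        result = closed_test(sample, cfg.alpha, calibration=cfg.calibration, plan=plan)
        hits += bool(np.any(result.rejected[: cfg.d0]))
    return _rate(hits, cfg.n_rep)


def experiment_grid(base: Model1Config, cells: list[dict]) -> list[dict]:
    """Run a list of configuration overrides and collect tidy result rows.

    Each cell dict overrides fields of ``base`` plus a mandatory
    ``"experiment"`` key in {"type1", "power", "fwer"}; returns one row
    per cell with the configuration and the estimated rate and SE.
    """
    runners = {"type1": type1_experiment, "power": power_experiment, "fwer": fwer_experiment}
    rows = []
    for cell in cells:
        cell = dict(cell)
        kind = cell.pop("experiment")
        cfg = replace(base, **cell)
        res = runners[kind](cfg)
        rows.append(
            {
                "experiment": kind,
                "d": cfg.d,
                "d0": cfg.d0,
                "delta": cfg.delta,
                "rho": cfg.rho,
                "n_a": cfg.n_a,
                "n_b": cfg.n_b,
                "calibration": cfg.calibration,
                "rate": res.rate,
                "se": res.se,
                "n_rep": res.n_rep,
            }
        )
    return rows
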